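"""Spatial weights, Gi*, bivariate Moran/LISA vs brute-force oracles.

The oracles are deliberately naive double loops over the weight matrix,
independent of the vectorized implementation they check.
"""

import numpy as np
import pandas as pd
import pytest

from yieldgap.spatial import (
    SpatialWeights,
    bivariate_lisa,
    bivariate_moran_global,
    build_contiguity_weights,
    classify_hotspot,
    getis_ord_gi_star,
    permutation_pvalue,
)
from yieldgap.synthetic import SimulationConfig, generate_counties


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def gi_star_bruteforce(x, w_dense):
    """Naive Gi* with self-inclusive weights (w_dense already includes self)."""
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(((x - xbar) ** 2).sum() / n)
    z = np.empty(n)
    for i in range(n):
        W = sum(w_dense[i, j] for j in range(n))
        S1 = sum(w_dense[i, j] ** 2 for j in range(n))
        num = sum(w_dense[i, j] * x[j] for j in range(n)) - xbar * W
        den = s * np.sqrt((n * S1 - W**2) / (n - 1))
        # a neighborhood covering the whole study area gives 0/0; define as 0
        z[i] = num / den if den > 0 else 0.0
    return z

def moran_bruteforce(x, y, w_dense):
    n = len(x)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    s0 = w_dense.sum()
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += w_dense[i, j] * zx[i] * zy[j]
    return total / s0

def lisa_bruteforce(x, y, w_dense):
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    return np.array(
        [zx[i] * sum(w_dense[i, j] * zy[j] for j in range(len(x))) for i in range(len(x))]
    )


def path3_weights():
    """3-node path graph with binary weights."""
    return SpatialWeights(ids=["a", "b", "c"], neighbors=[[1], [0, 2], [1]],
                          weights=[[1.0], [1.0, 1.0], [1.0]])


@pytest.fixture(scope="module")
def grid25():
    """5x5 county grid and its queen weights (25 counties, oracle-sized)."""
    cfg = SimulationConfig(seed=5, n_county_x=5, n_county_y=5,
                           cells_per_county_side=2, n_municipal_districts=0)
    counties = generate_counties(cfg)
    return counties, build_contiguity_weights(counties, rule="queen", row_standardize=True)


class TestContiguityWeights:
    def test_queen_center_has_eight_neighbors(self):
        cfg = SimulationConfig(seed=0, n_county_x=3, n_county_y=3,
                               cells_per_county_side=2, n_municipal_districts=0)
        counties = generate_counties(cfg)
        w = build_contiguity_weights(counties, rule="queen", row_standardize=False)
        center = w.ids.index("C005")
        assert len(w.neighbors[center]) == 8

    def test_rook_center_has_four_neighbors(self):
        cfg = SimulationConfig(seed=0, n_county_x=3, n_county_y=3,
                               cells_per_county_side=2, n_municipal_districts=0)
        counties = generate_counties(cfg)
        w = build_contiguity_weights(counties, rule="rook", row_standardize=False)
        center = w.ids.index("C005")
        assert len(w.neighbors[center]) == 4
        corner = w.ids.index("C001")
        assert len(w.neighbors[corner]) == 2

    def test_row_standardized_rows_sum_to_one(self, grid25):
        _, w = grid25
        for wt in w.weights:
            assert sum(wt) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_before_standardization(self, grid25):
        counties, _ = grid25
        w = build_contiguity_weights(counties, row_standardize=False)
        dense = w.to_sparse().toarray()
        np.testing.assert_array_equal(dense, dense.T)


class TestGiStar:
    def test_three_node_path_hand_values(self):
        """z = (-1.2247, 0, +1.2247) for x=(1,2,3) on a path with self-
        inclusive binary weights — the fully hand-computable case."""
        out = getis_ord_gi_star(np.array([1.0, 2.0, 3.0]), path3_weights())
        np.testing.assert_allclose(
            out["gi_star_z"].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )

    def test_matches_bruteforce_on_grid(self, grid25):
        counties, _ = grid25
        w = build_contiguity_weights(counties, row_standardize=False)
        rng = np.random.default_rng(11)
        x = rng.normal(size=w.n)
        dense = w.with_self().to_sparse().toarray()
        np.testing.assert_allclose(
            getis_ord_gi_star(x, w)["gi_star_z"].to_numpy(),
            gi_star_bruteforce(x, dense),
            atol=1e-10,
        )

    def test_label_invariance_under_county_reordering(self, grid25):
        counties, w = grid25
        rng = np.random.default_rng(2)
        x = rng.normal(size=w.n)
        base = getis_ord_gi_star(x, w).set_index("county_id")["gi_star_z"]
        perm = rng.permutation(w.n)
        shuffled = counties.iloc[perm].reset_index(drop=True)
        w2 = build_contiguity_weights(shuffled, row_standardize=True)
        x2 = pd.Series(x, index=w.ids).reindex(w2.ids).to_numpy()
        again = getis_ord_gi_star(x2, w2).set_index("county_id")["gi_star_z"]
        pd.testing.assert_series_equal(base.sort_index(), again.sort_index(), atol=1e-12)

    def test_sign_symmetry_swaps_hot_and_cold(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(3)
        x = rng.normal(size=w.n)
        a = getis_ord_gi_star(x, w)["hotspot_class"]
        b = getis_ord_gi_star(-x, w)["hotspot_class"]
        swap = {"hot99": "cold99", "hot95": "cold95", "hot90": "cold90", "ns": "ns",
                "cold90": "hot90", "cold95": "hot95", "cold99": "hot99"}
        assert [swap[c] for c in a] == list(b)

    def test_constant_input_rejected(self, grid25):
        _, w = grid25
        with pytest.raises(ValueError, match="variance"):
            getis_ord_gi_star(np.ones(w.n), w)

    def test_class_thresholds(self):
        z = np.array([2.7, 2.0, 1.7, 0.5, -1.7, -2.0, -2.7])
        assert list(classify_hotspot(z)) == [
            "hot99", "hot95", "hot90", "ns", "cold90", "cold95", "cold99"
        ]


def two_node_weights():
    return SpatialWeights(ids=["a", "b"], neighbors=[[1], [0]], weights=[[1.0], [1.0]])


class TestBivariateMoran:
    def test_two_node_hand_values(self):
        w = two_node_weights()
        x = np.array([1.0, -1.0])
        assert bivariate_moran_global(x, np.array([-1.0, 1.0]), w, seed=0).global_i == pytest.approx(1.0)
        assert bivariate_moran_global(x, np.array([1.0, -1.0]), w, seed=0).global_i == pytest.approx(-1.0)

    def test_reduces_to_univariate_moran(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(4)
        x = rng.normal(size=w.n)
        dense = w.to_sparse().toarray()
        got = bivariate_moran_global(x, x, w, n_perm=99, seed=0).global_i
        assert got == pytest.approx(moran_bruteforce(x, x, dense), abs=1e-10)

    def test_matches_bruteforce_on_grid(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=w.n), rng.normal(size=w.n)
        dense = w.to_sparse().toarray()
        got = bivariate_moran_global(x, y, w, n_perm=99, seed=0).global_i
        assert got == pytest.approx(moran_bruteforce(x, y, dense), abs=1e-10)

    def test_affine_invariance(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=w.n), rng.normal(size=w.n)
        a = bivariate_moran_global(x, y, w, n_perm=99, seed=0).global_i
        b = bivariate_moran_global(3.0 * x - 7.0, 0.5 * y + 2.0, w, n_perm=99, seed=0).global_i
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_rejected(self, grid25):
        _, w = grid25
        with pytest.raises(ValueError, match="variance"):
            bivariate_moran_global(np.ones(w.n), np.arange(w.n, dtype=float), w, seed=0)


class TestBivariateLisa:
    def test_two_node_local_values(self):
        w = two_node_weights()
        res = bivariate_lisa(
            np.array([1.0, -1.0]), np.array([-1.0, 1.0]), w, n_perm=99, seed=0
        )
        np.testing.assert_allclose(res.local_i, [1.0, 1.0])

    def test_matches_bruteforce_locals(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=w.n), rng.normal(size=w.n)
        res = bivariate_lisa(x, y, w, n_perm=99, seed=0)
        np.testing.assert_allclose(
            res.local_i, lisa_bruteforce(x, y, w.to_sparse().toarray()), atol=1e-10
        )

    def test_locals_sum_to_global(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=w.n), rng.normal(size=w.n)
        res = bivariate_lisa(x, y, w, n_perm=99, seed=0)
        s0 = w.to_sparse().sum()
        assert res.local_i.sum() / s0 == pytest.approx(res.global_i, abs=1e-12)

    def test_quadrant_classes_respect_alpha_gate(self, grid25):
        _, w = grid25
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=w.n), rng.normal(size=w.n)
        res = bivariate_lisa(x, y, w, n_perm=199, alpha=0.05, seed=0)
        insig = res.local_p > 0.05
        assert all(c == "ns" for c in res.lisa_class[insig])
        assert all(c in {"HH", "LL", "HL", "LH"} for c in res.lisa_class[~insig])


class TestPermutationPvalue:
    def test_boundary_when_observed_beats_all(self):
        assert permutation_pvalue(10.0, np.zeros(999) + 0.1) == pytest.approx(1 / 1000)

    def test_median_observed_near_half(self):
        null = np.linspace(-1, 1, 999)
        assert permutation_pvalue(0.0, null) == pytest.approx(1.0)
        assert 0.45 < permutation_pvalue(0.5, null) < 0.55

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(1.0, np.zeros(50))
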