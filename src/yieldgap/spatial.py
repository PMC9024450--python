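"""Spatial weights, hot-spot analysis, and bivariate spatial correlation.

Contiguity weights over county polygons (queen: any shared boundary point;
rook: shared boundary segment), optionally row-standardized.  On top of them:

* Getis–Ord Gi* — the self-inclusive local clustering statistic, scaled to a
  standard normal z, classifying counties into hot/cold spots at the 90/95/99%
  levels (|z| thresholds 1.65 / 1.96 / 2.58).
* Bivariate global Moran's I — the correlation between one variable and the
  spatial lag of another, I_xy = sum_ij w_ij zx_i zy_j / S0 with population-
  standardized scores; inference by conditional permutation (y shuffled over
  locations, x held fixed).
* Bivariate LISA — local I_i = zx_i * lag_i(zy), with HH/LL/HL/LH quadrant
  classes gated by the local conditional-permutation pseudo p-value.

All standardizations use the population (n-denominator) standard deviation,
matching the classical derivations of these statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from shapely.strtree import STRtree

__all__ = [
    "SpatialWeights",
    "build_contiguity_weights",
    "getis_ord_gi_star",
    "bivariate_moran_global",
    "bivariate_lisa",
    "permutation_pvalue",
]


@dataclass
class SpatialWeights:
    """Neighbor structure over an ordered set of county ids.

    ``neighbors[i]`` and ``weights[i]`` are aligned lists of neighbor indices
    and weights for the i-th id.  The neighbor relation is symmetric before
    row standardization.  ``include_self`` marks weight matrices that carry a
    self-neighbor (as Gi* requires).
    """

    ids: list[str]
    neighbors: list[list[int]]
    weights: list[list[float]]
    row_standardized: bool = False
    include_self: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def isolates(self) -> list[str]:
        return [self.ids[i] for i, nb in enumerate(self.neighbors) if not nb]

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb)
            vals.extend(wt)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def row_standardize(self) -> "SpatialWeights":
        """Return a copy whose rows sum to one (isolates stay empty)."""
        new_weights = []
        for wt in self.weights:
            s = sum(wt)
            new_weights.append([w / s for w in wt] if s > 0 else [])
        return SpatialWeights(
            ids=list(self.ids),
            neighbors=[list(nb) for nb in self.neighbors],
            weights=new_weights,
            row_standardized=True,
            include_self=self.include_self,
        )

    def with_self(self) -> "SpatialWeights":
        """Return a binary-plus-self copy (unit self-weight), as Gi* uses."""
        neighbors, weights = [], []
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            nb2, wt2 = list(nb), list(wt)
            if i not in nb2:
                nb2.append(i)
                wt2.append(1.0)
            neighbors.append(nb2)
            weights.append(wt2)
        return SpatialWeights(
            ids=list(self.ids),
            neighbors=neighbors,
            weights=weights,
            row_standardized=False,
            include_self=True,
        )


def build_contiguity_weights(
    counties: pd.DataFrame,
    rule: str = "queen",
    row_standardize: bool = True,
    allow_isolates: bool = False,
) -> SpatialWeights:
    """Polygon contiguity weights, deterministic in county_id order.

    queen: polygons sharing at least one boundary point are neighbors.
    rook: polygons sharing a boundary segment of positive length.
    """
    if rule not in {"queen", "rook"}:
        raise ValueError(f"unknown contiguity rule {rule!r}")
    frame = counties.sort_values("county_id").reset_index(drop=True)
    ids = frame["county_id"].tolist()
    geoms = frame["geometry"].tolist()
    tree = STRtree(geoms)
    neighbors: list[list[int]] = [[] for _ in ids]
    qi, qj = tree.query(geoms, predicate="intersects")
    for i, j in zip(qi, qj):
        if i >= j:
            continue
        inter = geoms[i].intersection(geoms[j])
        touch = not inter.is_empty
        if rule == "rook":
            touch = touch and inter.length > 0
        if touch:
            neighbors[i].append(int(j))
            neighbors[j].append(int(i))
    neighbors = [sorted(nb) for nb in neighbors]
    weights = [[1.0] * len(nb) for nb in neighbors]
    w = SpatialWeights(ids=ids, neighbors=neighbors, weights=weights)
    if w.isolates and not allow_isolates:
        raise ValueError(
            f"isolate counties with no neighbors: {w.isolates}; "
            "pass allow_isolates=True to proceed"
        )
    return w.row_standardize() if row_standardize else w


def _zscore(x: np.ndarray) -> np.ndarray:
    """Population-standardized scores; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population (n-denominator) sd
    if sd == 0:
        raise ValueError("zero variance: statistic undefined for constant input")
    return (x - x.mean()) / sd


_HOTSPOT_THRESHOLDS = [(2.58, "hot99", "cold99"), (1.96, "hot95", "cold95"), (1.65, "hot90", "cold90")]


def classify_hotspot(z: np.ndarray) -> np.ndarray:
    """Map z-scores to hot/cold classes at the 90/95/99% levels."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, "ns", dtype=object)
    for thr, hot, cold in _HOTSPOT_THRESHOLDS:
        out[(out == "ns") & (z >= thr)] = hot
        out[(out == "ns") & (z <= -thr)] = cold
    return out


def getis_ord_gi_star(
    x: np.ndarray, w: SpatialWeights, star: bool = True
) -> pd.DataFrame:
    """Getis–Ord Gi* (or Gi with ``star=False``) hot-spot statistic.

    Gi*_i = (sum_j w_ij x_j - Xbar W_i) / (S * sqrt((n sum_j w_ij^2 - W_i^2)/(n-1)))

    with W_i = sum_j w_ij and S the population standard deviation of x; for
    plain Gi the sums exclude i and use the leave-one-out mean/sd.  Returns a
    frame with z-scores, two-sided normal p-values, and hot/cold classes.
    """
    x = np.asarray(x, dtype=float)
    n = w.n
    if len(x) != n:
        raise ValueError("value vector length does not match weights")
    if n < 3:
        raise ValueError("Gi* needs at least 3 counties")
    if x.std() == 0:
        raise ValueError("zero variance: Gi* undefined for constant input")
    wm = (w.with_self() if star else w).to_sparse()
    if not star:
        wm.setdiag(0.0)
        wm.eliminate_zeros()
    z = np.empty(n)
    dense = wm.toarray()
    for i in range(n):
        wi = dense[i]
        if star:
            xbar, s2 = x.mean(), x.var()
            m = n
        else:
            others = np.arange(n) != i
            xbar = x[others].mean()
            s2 = x[others].var()
            m = n - 1
        s = np.sqrt(s2)
        W = wi.sum()
        S1 = (wi**2).sum()
        num = wi @ x - xbar * W
        den = s * np.sqrt((m * S1 - W**2) / (m - 1))
        z[i] = num / den if den > 0 else 0.0
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"county_id": w.ids, "gi_star_z": z, "p_value": p, "hotspot_class": classify_hotspot(z)}
    )


def permutation_pvalue(observed: float, null_draws: np.ndarray) -> float:
    """Two-sided pseudo p-value: (#(|null| >= |obs|) + 1) / (n_perm + 1)."""
    null_draws = np.asarray(null_draws, dtype=float)
    if len(null_draws) < 99:
        raise ValueError("need at least 99 permutations for a meaningful pseudo-p")
    exceed = int(np.sum(np.abs(null_draws) >= abs(observed)))
    return (exceed + 1) / (len(null_draws) + 1)


@dataclass
class BivariateMoranResult:
    """Global bivariate Moran's I plus optional local (LISA) components."""

    global_i: float
    pseudo_p: float
    ids: list[str]
    local_i: np.ndarray | None = None
    local_p: np.ndarray | None = None
    lisa_class: np.ndarray | None = None
    null_draws: np.ndarray = field(default=None, repr=False)

    def local_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "county_id": self.ids,
                "local_i": self.local_i,
                "local_p": self.local_p,
                "lisa_class": self.lisa_class,
            }
        )


def bivariate_moran_global(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
) -> BivariateMoranResult:
    """Bivariate global Moran's I of x against the spatial lag of y.

    I_xy = sum_ij w_ij zx_i zy_j / S0, S0 = sum of all weights.  With x == y
    this reduces to univariate Moran's I.  The permutation null shuffles y
    over locations while x stays fixed.
    """
    zx, zy = _zscore(x), _zscore(y)
    wm = w.to_sparse()
    s0 = wm.sum()
    observed = float(zx @ (wm @ zy) / s0)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = zx @ (wm @ rng.permutation(zy)) / s0
    return BivariateMoranResult(
        global_i=observed,
        pseudo_p=permutation_pvalue(observed, null),
        ids=list(w.ids),
        null_draws=null,
    )


def bivariate_lisa(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BivariateMoranResult:
    """Bivariate local Moran (LISA): I_i = zx_i * sum_j w_ij zy_j.

    Inference is conditional-permutation: for each county the neighbor values
    of zy are redrawn from the other n-1 locations, zx_i held fixed.  Classes
    come from the sign quadrant of (zx_i, lag_i), reported only where the
    local pseudo-p <= alpha ('ns' otherwise).  With row-standardized weights
    sum_i I_i / S0 equals the global I.
    """
    zx, zy = _zscore(x), _zscore(y)
    wm = w.to_sparse()
    s0 = wm.sum()
    lag = wm @ zy
    local = zx * lag
    rng = np.random.default_rng(seed)
    n = w.n
    local_p = np.empty(n)
    for i in range(n):
        nb = np.asarray(w.neighbors[i], dtype=int)
        wt = np.asarray(w.weights[i], dtype=float)
        keep = nb != i  # conditional scheme: i never draws itself
        nb, wt = nb[keep], wt[keep]
        if len(nb) == 0:
            local_p[i] = 1.0
            continue
        pool = np.delete(zy, i)
        draws = np.empty((n_perm, len(nb)))
        for k in range(n_perm):
            draws[k] = pool[rng.choice(len(pool), size=len(nb), replace=False)]
        null_local = zx[i] * (draws @ wt)
        local_p[i] = permutation_pvalue(local[i], null_local)
    quadrant = np.where(
        zx > 0, np.where(lag > 0, "HH", "HL"), np.where(lag > 0, "LH", "LL")
    ).astype(object)
    quadrant[local_p > alpha] = "ns"
    observed = float(np.sum(local) / s0)
    global_null = np.empty(n_perm)
    for k in range(n_perm):
        global_null[k] = zx @ (wm @ rng.permutation(zy)) / s0
    return BivariateMoranResult(
        global_i=observed,
        pseudo_p=permutation_pvalue(observed, global_null),
        ids=list(w.ids),
        local_i=local,
        local_p=local_p,
        lisa_class=quadrant,
        null_draws=global_null,
    )
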