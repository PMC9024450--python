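"""Ranking determinants of yield-gap change with a regression forest.

For each period the yield-gap change (YGC) is regressed on the 27 candidate
factors with a random forest; per-factor importances are normalized so the
top factor scores 1, the ten highest-scoring factors are flagged as key
factors, and each category's share of the top-ten slots gives its
contribution percentage.  Counties flagged as municipal districts or with
missing determinant values are excluded before fitting.

The default importance flavor is out-of-bag permutation importance (Breiman):
for each tree the increase in mean-squared error on its out-of-bag samples
when one factor is permuted, averaged over trees.  It is less biased toward
high-cardinality variables than impurity importance, which is kept as an
option for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

from .io_core import CATEGORY_MAP, DETERMINANT_VARS, logger


def _call_compat(fn, *args):
    """Call a forest helper across sklearn versions (sample_weight arg)."""
    try:
        return fn(*args)
    except TypeError:
        return fn(*args, None)

CATEGORIES = ["climatic", "socioeconomic", "land_use", "human_investment"]


@dataclass
class FactorMatrix:
    """Design matrix for one period: counties x 27 factors, response = YGC."""

    period: str
    county_ids: list[str]
    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("FactorMatrix must be complete (no missing cells)")
        if list(self.X.columns) != DETERMINANT_VARS:
            missing = set(DETERMINANT_VARS) - set(self.X.columns)
            if missing:
                raise ValueError(f"missing determinant columns: {sorted(missing)}")
            self.X = self.X[DETERMINANT_VARS]


@dataclass
class ImportanceResult:
    """Per-factor importance scores for one period."""

    period: str
    table: pd.DataFrame  # columns: factor, raw_importance, score, rank, top10, category

    @property
    def top10(self) -> list[str]:
        return self.table.loc[self.table["top10"], "factor"].tolist()


def assemble_factor_matrix(
    panel: pd.DataFrame,
    ygc: pd.DataFrame,
    period: tuple[str, str],
    counties: pd.DataFrame | None = None,
    min_counties: int = 20,
) -> FactorMatrix:
    """Join determinants (at the period's start epoch) with the period's YGC.

    Drops municipal districts (when ``counties`` carries the flag) and any
    county with a missing determinant value; aborts below ``min_counties``
    retained rows because the forest would be unreliable.
    """
    start, end = period
    sub = ygc[(ygc["epoch_start"] == start) & (ygc["epoch_end"] == end)]
    if sub.empty:
        raise ValueError(f"period {start}-{end} absent from the gap-change table")
    det = panel[panel["epoch"] == start][["county_id"] + DETERMINANT_VARS]
    merged = sub[["county_id", "ygc"]].merge(det, on="county_id")
    if counties is not None and "is_municipal_district" in counties.columns:
        districts = set(counties.loc[counties["is_municipal_district"], "county_id"])
        merged = merged[~merged["county_id"].isin(districts)]
    complete = ~merged[DETERMINANT_VARS].isna().any(axis=1) & merged["ygc"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("period %s-%s: dropped %d counties with missing determinants", start, end, n_dropped)
    merged = merged[complete].sort_values("county_id").reset_index(drop=True)
    if len(merged) < min_counties:
        raise ValueError(
            f"only {len(merged)} counties retained for {start}-{end}; "
            f"need >= {min_counties} for a reliable importance model"
        )
    return FactorMatrix(
        period=f"{start}-{end}",
        county_ids=merged["county_id"].tolist(),
        X=merged[DETERMINANT_VARS],
        y=merged["ygc"].to_numpy(),
    )


def oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breiman's out-of-bag permutation importance for a fitted forest.

    For each tree and factor: MSE on the tree's out-of-bag samples after
    permuting that factor, minus the baseline OOB MSE; averaged over trees.
    """
    n_samples = X.shape[0]
    n_bootstrap = _call_compat(_get_n_samples_bootstrap, n_samples, forest.max_samples)
    importances = np.zeros(X.shape[1])
    n_used = 0
    for tree in forest.estimators_:
        oob = _call_compat(_generate_unsampled_indices, tree.random_state, n_samples, n_bootstrap)
        if len(oob) < 2:
            continue
        n_used += 1
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean((tree.predict(X_oob) - y_oob) ** 2)
        for j in range(X.shape[1]):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(oob)), j]
            importances[j] += np.mean((tree.predict(X_perm) - y_oob) ** 2) - base
    if n_used == 0:
        raise ValueError("no tree had usable out-of-bag samples")
    return importances / n_used


def fit_importance(
    fm: FactorMatrix,
    n_trees: int = 1000,
    seed: int = 0,
    method: str = "oob_permutation",
    category_map: dict[str, str] = CATEGORY_MAP,
    k: int = 10,
) -> ImportanceResult:
    """Fit the regression forest and score factor importance for one period.

    ``method`` is 'oob_permutation' (default) or 'impurity'.  Scores are
    normalized to [0, 1] with the top factor at 1; the ``k`` highest scores
    are flagged as key factors (ties at rank k broken by factor name, logged).
    """
    if np.std(fm.y) == 0:
        raise ValueError("constant response: importance undefined")
    X = fm.X.to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, bootstrap=True, n_jobs=1
    )
    forest.fit(X, fm.y)
    if method == "oob_permutation":
        raw = oob_permutation_importance(forest, X, fm.y, np.random.default_rng(seed))
    elif method == "impurity":
        raw = forest.feature_importances_
    else:
        raise ValueError(f"unknown importance method {method!r}")
    score = normalize_scores(raw)
    factors = list(fm.X.columns)
    table = pd.DataFrame({"factor": factors, "raw_importance": raw, "score": score})
    # stable rank: score descending, factor name as deterministic tie-break
    table = table.sort_values(["score", "factor"], ascending=[False, True]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["top10"] = table["rank"] <= k
    if len(table) > k and table.loc[k - 1, "score"] == table.loc[k, "score"]:
        logger.info(
            "period %s: tie at rank %d broken by factor name (%s kept over %s)",
            fm.period, k, table.loc[k - 1, "factor"], table.loc[k, "factor"],
        )
    table["category"] = table["factor"].map(category_map)
    return ImportanceResult(period=fm.period, table=table)


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Scale raw importances into [0, 1]: floor negatives at 0, divide by max.

    Negative out-of-bag permutation importances mean permuting the factor
    helped — i.e. pure noise — and are floored to 0 before scaling.
    """
    raw = np.asarray(raw, dtype=float)
    floored = np.maximum(raw, 0.0)
    top = floored.max()
    if top == 0:
        raise ValueError("all importances are zero or negative; nothing to rank")
    return floored / top


def top_k_frequency(results: list[ImportanceResult], k: int = 10) -> pd.DataFrame:
    """Count, per factor, in how many periods it lands in the top k."""
    if len(results) < 2:
        raise ValueError("need at least 2 periods to count frequencies")
    counts = {f: 0 for f in DETERMINANT_VARS}
    for res in results:
        for f in res.top10:
            counts[f] += 1
    out = pd.DataFrame({"factor": list(counts), "frequency": list(counts.values())})
    out["category"] = out["factor"].map(CATEGORY_MAP)
    return out.sort_values(["frequency", "factor"], ascending=[False, True]).reset_index(drop=True)


def category_contribution(
    result: ImportanceResult, category_map: dict[str, str] = CATEGORY_MAP
) -> pd.Series:
    """Percent of top-ten slots held by each factor category (sums to 100)."""
    top = result.table[result.table["top10"]]
    k = len(top)
    shares = top["factor"].map(category_map).value_counts()
    return pd.Series(
        {cat: 100.0 * shares.get(cat, 0) / k for cat in CATEGORIES}, name=result.period
    )
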