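"""Yield-gap statistics: YGAP, RYGAP, YGC, bin summaries, change classes.

County-level definitions (all in t ha^-1 except RYGAP in percent):

    YGAP  = mean potential yield (YS) - mean actual farm yield
    RYGAP = 100 * YGAP / mean potential yield
    YGC   = YGAP at end of period - YGAP at start  (negative = gap closing)

Gap magnitudes are summarized over counties with the half-open bin scheme
<3 | 3-6 | 6-9 | 9-12 | >=12 t ha^-1; sub-period and full-period gap changes
get their own class schemes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import logger

#: half-open [lo, hi) YGAP bin edges, t ha^-1
GAP_BIN_EDGES = [-np.inf, 3.0, 6.0, 9.0, 12.0, np.inf]
GAP_BIN_LABELS = ["<3", "3-6", "6-9", "9-12", ">=12"]

#: YGC class edges: sub-period and full-period schemes
YGC_SUBPERIOD_EDGES = [-np.inf, -3.0, -2.0, -1.0, 0.0, 1.0, np.inf]
YGC_FULLPERIOD_EDGES = [-np.inf, -6.0, -4.0, -2.0, 0.0, 2.0, np.inf]
YGC_CLASS_LABELS = ["L1", "L2", "L3", "L4", "L5", "L6"]


def yield_gap(ys_mean, yfarm_mean):
    """YGAP = mean potential - mean farm yield, t ha^-1.

    A negative gap (farm exceeding modeled potential) is retained and flagged
    by the caller, never clipped; missing inputs give missing output.
    """
    return np.asarray(ys_mean, dtype=float) - np.asarray(yfarm_mean, dtype=float)


def relative_yield_gap(ygap, ys_mean):
    """RYGAP = 100 * YGAP / YS-mean, percent; missing where YS-mean <= 0."""
    ygap = np.asarray(ygap, dtype=float)
    ys = np.asarray(ys_mean, dtype=float)
    out = np.full(np.broadcast(ygap, ys).shape, np.nan)
    ok = ys > 0
    np.divide(100.0 * ygap, ys, out=out, where=ok)
    if np.any(~ok & ~np.isnan(ys)):
        logger.warning("RYGAP undefined where mean potential yield is zero; set missing")
    return out if out.shape else float(out)


def county_yield_table(
    potential: pd.DataFrame, panel: pd.DataFrame, epochs: list[str] | None = None
) -> pd.DataFrame:
    """Join per-county potential and farm yields, compute YGAP/RYGAP/bins.

    ``potential`` carries columns (county_id, epoch, ys_mean [t ha^-1]);
    ``panel`` carries (county_id, epoch, actual_farm_yield [t ha^-1]).
    """
    table = potential.merge(
        panel[["county_id", "epoch", "actual_farm_yield"]], on=["county_id", "epoch"]
    ).rename(columns={"actual_farm_yield": "yfarm_mean"})
    if epochs is not None:
        table = table[table["epoch"].isin(epochs)]
    table["ygap"] = yield_gap(table["ys_mean"], table["yfarm_mean"])
    table["rygap"] = relative_yield_gap(table["ygap"].to_numpy(), table["ys_mean"].to_numpy())
    table["gap_bin"] = bin_labels(table["ygap"].to_numpy())
    n_neg = int((table["ygap"] < 0).sum())
    if n_neg:
        logger.warning("%d county-epochs have farm yield above modeled potential", n_neg)
    return table.reset_index(drop=True)


def bin_labels(
    values: np.ndarray,
    edges: list[float] = GAP_BIN_EDGES,
    labels: list[str] = GAP_BIN_LABELS,
) -> np.ndarray:
    """Assign half-open [lo, hi) bin labels; NaN stays unlabeled (None)."""
    _check_edges(edges, labels)
    values = np.asarray(values, dtype=float)
    idx = np.digitize(values, edges[1:-1], right=False)
    out = np.array([labels[i] for i in idx], dtype=object)
    out[np.isnan(values)] = None
    return out


def bin_counties(
    values: np.ndarray,
    edges: list[float] = GAP_BIN_EDGES,
    labels: list[str] = GAP_BIN_LABELS,
    total: int | None = None,
) -> pd.DataFrame:
    """Count counties per half-open bin and express ratios in percent.

    ``total`` defaults to the number of non-missing values; ratios are
    rounded to 2 decimals for report parity (full precision is trivially
    recomputable from the counts).
    """
    lab = bin_labels(values, edges, labels)
    lab = lab[lab != None]  # noqa: E711  — drop unlabeled missing values
    if total is None:
        total = len(lab)
    counts = pd.Series(lab).value_counts().reindex(labels, fill_value=0)
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts.to_numpy(),
            "ratio_percent": np.round(100.0 * counts.to_numpy() / total, 2),
        }
    )


def _check_edges(edges: list[float], labels: list[str]) -> None:
    if len(edges) != len(labels) + 1:
        raise ValueError("need len(labels) + 1 edges")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing (no overlap)")


def yield_gap_change(
    table: pd.DataFrame,
    period: tuple[str, str],
    scheme: str | None = None,
) -> pd.DataFrame:
    """YGC per county over (epoch_start, epoch_end), with change classes.

    ``scheme`` picks the class edges: 'sub' for consecutive-epoch periods,
    'full' for the whole study window; None skips classification.  Counties
    missing either endpoint are omitted with a log entry.  Sub-period YGCs
    telescope: their sum over consecutive periods equals the full-period YGC
    exactly (a float identity since terms cancel pairwise).
    """
    start, end = period
    for ep in period:
        if ep not in set(table["epoch"]):
            raise ValueError(f"epoch {ep!r} absent from county yield table")
    a = table[table["epoch"] == start].set_index("county_id")["ygap"]
    b = table[table["epoch"] == end].set_index("county_id")["ygap"]
    common = a.index.intersection(b.index)
    dropped = a.index.symmetric_difference(b.index)
    if len(dropped):
        logger.info("YGC %s-%s: %d counties missing an endpoint, omitted", start, end, len(dropped))
    ygc = (b.loc[common] - a.loc[common]).dropna()
    out = pd.DataFrame(
        {"county_id": ygc.index, "epoch_start": start, "epoch_end": end, "ygc": ygc.to_numpy()}
    )
    if scheme is not None:
        edges = YGC_SUBPERIOD_EDGES if scheme == "sub" else YGC_FULLPERIOD_EDGES
        out["change_class"] = bin_labels(out["ygc"].to_numpy(), edges, YGC_CLASS_LABELS)
    return out.reset_index(drop=True)


def gap_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch min/max/mean YGAP plus bin counts and ratios."""
    rows = []
    for epoch, sub in table.groupby("epoch", sort=True):
        vals = sub["ygap"].to_numpy()
        binned = bin_counties(vals)
        row = {
            "epoch": epoch,
            "maximum": np.round(np.nanmax(vals), 2),
            "minimum": np.round(np.nanmin(vals), 2),
            "mean": np.round(np.nanmean(vals), 2),
        }
        for _, b in binned.iterrows():
            row[f"n_{b['bin']}"] = int(b["count"])
            row[f"ratio_{b['bin']}"] = b["ratio_percent"]
        rows.append(row)
    return pd.DataFrame(rows)
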