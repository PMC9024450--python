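"""High-potential-county screening and full-pipeline orchestration.

Counties whose relative yield gap in the final epoch exceeds a threshold
(default 30%, strictly greater-than) and that are not municipal districts are
flagged as priority areas for yield improvement.  For the selected set, the
incremental-production scenario asks how many extra tons of grain a fixed
relative uplift of the *actual* farm yield (default +5%) would add, given
each county's sown grain area.

``run_pipeline`` wires the whole chain — simulate, potential yield, gap
statistics, spatial clustering, determinant ranking, screening — into one
reproducible run directory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import determinants as det
from . import gaps, spatial, synthetic
from .io_core import logger
from .potential import StepModelParams, county_mean_potential, potential_yield_chain


@dataclass
class ScreeningConfig:
    """Thresholds of the screening and uplift scenario."""

    rygap_threshold: float = 30.0  # percent, strictly greater-than
    exclude_municipal_districts: bool = True
    uplift: float = 0.05  # fraction of actual farm yield

    def __post_init__(self) -> None:
        if not 0 < self.rygap_threshold < 100:
            raise ValueError("rygap_threshold must be in (0, 100) percent")
        if not 0 < self.uplift < 1:
            raise ValueError("uplift must be a fraction in (0, 1)")


def screen_high_gap_counties(
    table: pd.DataFrame,
    counties: pd.DataFrame | None = None,
    config: ScreeningConfig = ScreeningConfig(),
) -> pd.DataFrame:
    """Select counties with RYGAP strictly above the threshold.

    ``table`` is the county yield table restricted to (or filtered here for)
    the final epoch.  Municipal districts are dropped when configured; the
    result is ordered by RYGAP descending.  Counties at exactly the threshold
    are excluded and logged.
    """
    sub = table.copy()
    at_bar = sub[sub["rygap"] == config.rygap_threshold]
    if len(at_bar):
        logger.info(
            "counties exactly at the %.1f%% threshold excluded: %s",
            config.rygap_threshold,
            at_bar["county_id"].tolist(),
        )
    sub = sub[sub["rygap"] > config.rygap_threshold]
    if config.exclude_municipal_districts and counties is not None:
        districts = set(counties.loc[counties["is_municipal_district"], "county_id"])
        sub = sub[~sub["county_id"].isin(districts)]
    return sub.sort_values("rygap", ascending=False).reset_index(drop=True)


def incremental_production(
    selected: pd.DataFrame, uplift: float = 0.05
) -> float:
    """Extra grain (tons) from uplifting actual yields in selected counties.

    sum over counties of sown_area_grain [ha] * actual farm yield [t ha^-1]
    * uplift.  Counties with a missing sown area are skipped with a warning.
    """
    area = selected["sown_area_grain"].to_numpy(dtype=float)
    yld = selected["yfarm_mean"].to_numpy(dtype=float)
    ok = ~np.isnan(area) & ~np.isnan(yld)
    if (~ok).any():
        logger.warning(
            "skipping %d counties with missing sown area or yield", int((~ok).sum())
        )
    return float(np.sum(area[ok] * yld[ok] * uplift))


def run_pipeline(
    outdir: str | Path,
    sim_config: synthetic.SimulationConfig | None = None,
    model_params: StepModelParams = StepModelParams(),
    screening: ScreeningConfig = ScreeningConfig(),
    n_perm: int = 999,
    n_trees: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Synthetic end-to-end run: simulate -> potential -> gap -> cluster ->
    determinants -> identify; all stage outputs land in ``outdir``.

    Returns a dict of the in-memory results.  Deterministic under the
    simulation seed (all downstream seeds derive from it).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or synthetic.SimulationConfig()
    seed = cfg.seed
    stage = "simulate"
    try:
        counties = synthetic.generate_counties(cfg)
        fields = synthetic.generate_climate_fields(cfg, counties)
        panel_base = synthetic.generate_determinant_panel(cfg, counties)

        stage = "potential"
        ys_rows = []
        for epoch in cfg.epochs:
            grid = potential_yield_chain(fields[epoch], model_params)
            ys_rows.append(county_mean_potential(grid, fields[epoch].landuse, counties))
        ys_means = pd.concat(ys_rows, ignore_index=True)
        panel, truth = synthetic.generate_farm_yields(cfg, ys_means, panel_base)
        synthetic.write_fixture_set(outdir / "inputs", cfg, counties, fields, panel, truth)
        ys_means.to_csv(outdir / "potential_by_county.csv", index=False)

        stage = "gap"
        ytable = gaps.county_yield_table(ys_means, panel)
        ytable.to_csv(outdir / "county_yield_table.csv", index=False)
        epochs = list(cfg.epochs)
        periods = list(zip(epochs[:-1], epochs[1:]))
        ygc_parts = [gaps.yield_gap_change(ytable, p, scheme="sub") for p in periods]
        full_ygc = gaps.yield_gap_change(ytable, (epochs[0], epochs[-1]), scheme="full")
        ygc = pd.concat(ygc_parts + [full_ygc], ignore_index=True)
        ygc.to_csv(outdir / "gap_change_table.csv", index=False)
        gaps.gap_summary(ytable).to_csv(outdir / "gap_summary.csv", index=False)

        stage = "cluster"
        w = spatial.build_contiguity_weights(counties, rule="queen", row_standardize=True)
        order = pd.Index(w.ids)
        hot_frames = {}
        for epoch in epochs:
            vals = (
                ytable[ytable["epoch"] == epoch]
                .set_index("county_id")["ygap"]
                .reindex(order)
                .to_numpy()
            )
            hs = spatial.getis_ord_gi_star(vals, w)
            hs.to_csv(outdir / f"hotspot_{epoch}.csv", index=False)
            hot_frames[epoch] = hs
        bimoran = {}
        for k, ((a0, a1), (b0, b1)) in enumerate(zip(periods[:-1], periods[1:])):
            x = _period_values(ygc, a0, a1, order)
            y = _period_values(ygc, b0, b1, order)
            res = spatial.bivariate_lisa(x, y, w, n_perm=n_perm, alpha=alpha, seed=seed + 1000 + k)
            frame = res.local_frame()
            frame.insert(1, "global_i", res.global_i)
            frame.insert(2, "global_pseudo_p", res.pseudo_p)
            frame.to_csv(outdir / f"bimoran_{a0}-{a1}_vs_{b0}-{b1}.csv", index=False)
            bimoran[f"{a0}-{a1}|{b0}-{b1}"] = res

        stage = "determinants"
        importance = []
        for p in periods + [(epochs[0], epochs[-1])]:
            fm = det.assemble_factor_matrix(panel, ygc, p, counties=counties)
            res = det.fit_importance(fm, n_trees=n_trees, seed=seed + 2000)
            res.table.to_csv(outdir / f"importance_{p[0]}-{p[1]}.csv", index=False)
            importance.append(res)
        freq = det.top_k_frequency(importance)
        freq.to_csv(outdir / "top10_frequency.csv", index=False)
        contrib = pd.DataFrame([det.category_contribution(r) for r in importance])
        contrib.index.name = "period"
        contrib.to_csv(outdir / "category_contribution.csv")

        stage = "identify"
        final = ytable[ytable["epoch"] == epochs[-1]].merge(
            panel[panel["epoch"] == epochs[-1]][["county_id", "sown_area_grain"]],
            on="county_id",
        )
        selected = screen_high_gap_counties(final, counties, screening)
        selected.to_csv(outdir / "selected_counties.csv", index=False)
        extra_tons = incremental_production(selected, screening.uplift)
        summary = {
            "n_counties": len(counties),
            "n_selected": len(selected),
            "incremental_production_tons": extra_tons,
            "mean_ygap_by_epoch": {
                e: float(ytable.loc[ytable["epoch"] == e, "ygap"].mean()) for e in epochs
            },
        }
        with open(outdir / "run_summary.yaml", "w") as fh:
            yaml.safe_dump(
                {**summary, "sim_config": asdict(cfg), "screening": asdict(screening)}, fh
            )
    except Exception as exc:  # annotate failures with the stage that broke
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {
        "config": cfg,
        "counties": counties,
        "fields": fields,
        "panel": panel,
        "truth": truth,
        "ys_means": ys_means,
        "yield_table": ytable,
        "ygc": ygc,
        "hotspots": hot_frames,
        "bimoran": bimoran,
        "importance": importance,
        "top10_frequency": freq,
        "category_contribution": contrib,
        "selected": selected,
        "summary": summary,
    }


def _period_values(
    ygc: pd.DataFrame, start: str, end: str, order: pd.Index
) -> np.ndarray:
    sub = ygc[(ygc["epoch_start"] == start) & (ygc["epoch_end"] == end)]
    return sub.set_index("county_id")["ygc"].reindex(order).to_numpy()
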