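"""End-to-end orchestration of the analysis stages.

Stage order: (simulate) → resolve-branches → tip-context → drift-correct
→ motility → fit-model.  Every stage reads only declared inputs and
writes only into the configured output directory; a stage failure aborts
the stages downstream of it and is recorded in the machine-readable run
report.  All analysis constants (edge margin, distance split, regression
threshold, horizontal angle rule) live in the config with the published
defaults, never hard-coded in stage logic, and a fixed config + seed
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import drift, motility, simulate as sim, tipgeom
from .branching import resolve_dataset
from .io import Dataset, read_dataset, write_dataset
from .model import TipDistanceModel

logger = logging.getLogger("capmotion.pipeline")

ALL_STAGES = ("simulate", "resolve", "context", "drift", "motility", "fit")


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run; defaults are the published constants."""

    data_dir: str = "data"
    out_dir: str = "out"
    stages: tuple = ALL_STAGES[1:]          # simulate is opt-in
    scenario: dict = field(default_factory=dict)  # SyntheticScenario overrides
    edge_margin: float = motility.EDGE_MARGIN_UM
    distance_split: float = motility.DISTANCE_SPLIT_UM
    regression_threshold: float = motility.REGRESSION_THRESHOLD_UM
    d_max: float | None = None
    edge_exclude_fit: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed, "ok": True}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if not report["ok"]:
            report["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        try:
            rec = _STAGE_FUNCS[stage](config, state, out_dir)
            rec["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and abort downstream
            logger.error("stage %s failed: %s", stage, exc)
            rec = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            report["ok"] = False
        report["stages"][stage] = rec
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _load(config: PipelineConfig, state: dict) -> Dataset:
    if "dataset" not in state:
        state["dataset"] = read_dataset(config.data_dir)
    return state["dataset"]


def _stage_simulate(config, state, out_dir):
    scenario = sim.SyntheticScenario(**{"seed": config.seed, **config.scenario})
    dataset, ledger = sim.simulate(scenario)
    write_dataset(dataset, config.data_dir)
    state["dataset"] = dataset
    state["ledger"] = ledger
    return {"n_spots": int(len(dataset.cells)), "n_divisions": int(len(ledger.divisions))}


def _stage_resolve(config, state, out_dir):
    dataset = _load(config, state)
    resolved, links = resolve_dataset(dataset.cells)
    state["resolved"] = resolved
    resolved.to_csv(out_dir / "segments.csv", index=False)
    links.to_csv(out_dir / "segment_links.csv", index=False)
    return {
        "n_spots": int(len(resolved)),
        "n_tracks": int(resolved.groupby(["sample", "crop"])["track"].nunique().sum()),
        "n_segments": int(len(links)),
    }


def _stage_context(config, state, out_dir):
    dataset = _load(config, state)
    resolved_ds = Dataset(
        state["resolved"], dataset.tip_clouds, dataset.tip_ends,
        dataset.attachments, dataset.annotated_tracks, dataset.metadata,
    )
    context = tipgeom.compute_tip_context(resolved_ds)
    state["context"] = context
    context.to_csv(out_dir / "context.csv", index=False)
    rec = {"n_spots": int(len(context))}
    if "attachment" in context.columns:
        rec["n_annotated"] = int((context["attachment"] != "unannotated").sum())
        rec["n_attached"] = int((context["attachment"] == "attached").sum())
        rec["n_horizontal"] = int(context["is_horizontal"].sum())
    return rec


def _stage_drift(config, state, out_dir):
    dataset = _load(config, state)
    corrected = drift.correct_dataset(state["resolved"], dataset.tip_ends)
    state["corrected"] = corrected
    corrected.to_csv(out_dir / "corrected.csv", index=False)
    return {"n_spots": int(len(corrected))}


def _stage_motility(config, state, out_dir):
    dataset = _load(config, state)
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    step_min = dataset.metadata.get("step_minutes", {})
    raw, corrected = state["resolved"], state["corrected"]

    msd_parts = []
    for label, cells in (("raw", raw), ("corrected", corrected)):
        curve = motility.aggregate_msd(cells, step_min)
        curve.insert(0, "variant", label)
        msd_parts.append(curve)
    pd.concat(msd_parts, ignore_index=True).to_csv(stats_dir / "msd.csv", index=False)

    autoc = motility.aggregate_autocorrelation(corrected, step_min)
    autoc.to_csv(stats_dir / "autocorr.csv", index=False)

    speeds = motility.instantaneous_speeds(corrected)
    het = motility.speed_heterogeneity(speeds)
    (stats_dir / "heterogeneity.txt").write_text(str(het) + "\n")

    context = state["context"]
    keep = motility.exclude_near_edge(context, dataset.crop_bounds, config.edge_margin)
    moves_all = motility.tip_directed_movement(context, corrected)
    kept_keys = set(
        map(tuple, context.loc[keep, ["sample", "crop", "track", "branch", "time"]].itertuples(index=False))
    )
    key_cols = ["sample", "crop", "track", "branch", "time"]
    in_keep = moves_all[key_cols].apply(tuple, axis=1).isin(kept_keys)
    moves = moves_all[in_keep].reset_index(drop=True)
    state["moves"] = moves
    attraction = motility.attraction_repulsion_tests(moves, config.distance_split)
    slope, pval = motility.distance_trend_regression(moves, config.regression_threshold)
    attraction.to_csv(stats_dir / "attraction.csv", index=False)
    (stats_dir / "distance_trend.json").write_text(
        json.dumps({"slope": slope, "p": pval}, indent=2)
    )
    return {
        "n_speeds": int(len(speeds)),
        "rss_reduction_percent": het.rss_reduction_percent,
        "n_moves": int(len(moves)),
        "n_edge_excluded": int((~keep).sum()),
        "far_mean_m": float(attraction.loc[1, "mean_m"]),
        "near_mean_m": float(attraction.loc[0, "mean_m"]),
    }


def _stage_fit(config, state, out_dir):
    dataset = _load(config, state)
    context = state["context"]
    if config.edge_exclude_fit:
        keep = motility.exclude_near_edge(context, dataset.crop_bounds, config.edge_margin)
        context = context[keep]
    distances = context["tip_distance"].to_numpy(float)
    model = TipDistanceModel(distances, d_max=config.d_max)
    res = model.fit()
    simp = res.simplified()
    payload = {
        "n": res.nobs,
        "d_max": model.d_max,
        "estimates": dict(zip(("d1", "d2", "k1", "k2"), map(float, res.params))),
        "standard_errors": dict(zip(("d1", "d2", "k1", "k2"), map(float, res.bse))),
        "log_likelihood": res.llf,
        "converged": res.converged,
        "simplified_profile": {"d1": simp.d1, "d2": simp.d2, "k1": simp.k1, "k2": simp.k2},
    }
    (out_dir / "fit.json").write_text(json.dumps(payload, indent=2, allow_nan=True))
    state["fit"] = res
    return {"k1": float(res.params[2]), "k2": float(res.params[3]), "converged": res.converged}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "resolve": _stage_resolve,
    "context": _stage_context,
    "drift": _stage_drift,
    "motility": _stage_motility,
    "fit": _stage_fit,
}
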