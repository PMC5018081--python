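"""Motility statistics: MSD, velocity autocorrelation, speed heterogeneity,
and the tip attraction/repulsion analysis.

Mean squared displacement (MSD) over a time difference τ is the average
squared straight-line displacement; a linear MSD–τ relationship indicates
Brownian motion (slope = diffusion rate), upward curvature persistent
directed movement, downward curvature confinement.  Velocity
autocorrelation measures short-term directional persistence.  Axial (z)
resolution in confocal stacks is much poorer than lateral resolution and
produces a jitter artefact — negative single-step autocorrelation in z
only — so autocorrelation and instantaneous speeds are computed in the
horizontal plane, while MSD, insensitive to such short-term noise, is
computed in 3D.

The attraction/repulsion statistic scores, per spot, the component of the
drift-corrected movement over the subsequent time step along the direction
to the nearest tip-cloud point (positive = toward the tip).  This is used
instead of the change in tip distance because, with a complex tip surface,
random motion does not give equal chances of the distance increasing or
decreasing.  Spots within 1 µm of the lateral crop edge are excluded
(their outward movement can leave the imaged volume, biasing the score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("capmotion.motility")

_COORDS = ["pos_x", "pos_y", "pos_z"]
_SEGKEY = ["sample", "crop", "track", "branch"]

#: defaults matching the published analysis constants
EDGE_MARGIN_UM = 1.0
DISTANCE_SPLIT_UM = 10.0
REGRESSION_THRESHOLD_UM = 15.0


# ---------------------------------------------------------------------------
# MSD and velocity autocorrelation
# ---------------------------------------------------------------------------

def msd(positions, tau: int) -> float | None:
    """Mean squared 3D displacement of one track at lag *tau* (µm²).

    *positions* are consecutive per-step positions, shape ``(n, 3)``.
    Returns ``None`` when the track is shorter than ``tau + 1`` positions
    (the track is excluded, not counted as zero).
    """
    p = np.asarray(positions, dtype=float).reshape(-1, 3)
    if tau < 1 or len(p) < tau + 1:
        return None
    disp = p[tau:] - p[:-tau]
    return float(np.mean(np.sum(disp**2, axis=1)))


def velocity_autocorrelation(positions, tau: int) -> float | None:
    """Normalised horizontal velocity autocorrelation of one track at lag *tau*.

    Step vectors are the horizontal (xy) per-step displacements; the mean
    dot product of steps separated by *tau* is normalised by the track's
    mean squared single-step horizontal displacement.  A constant-velocity
    track gives 1 at every lag.  Returns ``None`` for tracks too short
    (< tau + 2 positions) or with all-zero steps (excluded with a warning).
    """
    p = np.asarray(positions, dtype=float).reshape(-1, 3)[:, :2]
    if tau < 1 or len(p) < tau + 2:
        return None
    v = np.diff(p, axis=0)
    denom = np.mean(np.sum(v**2, axis=1))
    if denom == 0.0:
        logger.warning("track with zero horizontal movement excluded from autocorrelation")
        return None
    num = np.mean(np.sum(v[:-tau] * v[tau:], axis=1))
    return float(num / denom)


def _segments_positions(cells: pd.DataFrame):
    for key, seg in cells.groupby(_SEGKEY, sort=True):
        yield key, seg.sort_values("time", kind="mergesort")[_COORDS].to_numpy(float)


def _per_track_curve(tracks, taus, fn) -> pd.DataFrame:
    rows = []
    for tau in taus:
        vals = [v for v in (fn(p, tau) for p in tracks) if v is not None]
        if vals:
            rows.append({"tau": tau, "value": float(np.mean(vals)), "n_tracks": len(vals)})
    return pd.DataFrame(rows, columns=["tau", "value", "n_tracks"])


def aggregate_msd(cells: pd.DataFrame, step_minutes_of: dict, taus=None) -> pd.DataFrame:
    """MSD curves averaged across tracks, grouped by time-step length.

    Per-track MSD is computed first and then averaged, unweighted, across
    all tracks contributing at each lag.  Because a lag of τ steps means a
    different wall-clock interval at 15 vs 20 minutes per step, aggregation
    is always performed separately per ``step_minutes`` group.  Returns
    columns ``step_minutes, tau, msd, n_tracks``.
    """
    return _aggregate(cells, step_minutes_of, taus, msd, "msd")


def aggregate_autocorrelation(cells: pd.DataFrame, step_minutes_of: dict, taus=None) -> pd.DataFrame:
    """Horizontal velocity autocorrelation curves per step-length group."""
    return _aggregate(cells, step_minutes_of, taus, velocity_autocorrelation, "autocorr")


def _aggregate(cells, step_minutes_of, taus, fn, name) -> pd.DataFrame:
    samples = cells["sample"].unique()
    missing = [s for s in samples if s not in step_minutes_of]
    if missing:
        raise ValidationError(f"step_minutes unknown for sample(s) {missing}")
    out = []
    group_of = {s: int(step_minutes_of[s]) for s in samples}
    for step_min in sorted(set(group_of.values())):
        grp_cells = cells[cells["sample"].map(group_of) == step_min]
        tracks = [p for _, p in _segments_positions(grp_cells)]
        if taus is None:
            longest = max((len(p) for p in tracks), default=1)
            use_taus = range(1, longest)
        else:
            use_taus = taus
        curve = _per_track_curve(tracks, use_taus, fn)
        curve.insert(0, "step_minutes", step_min)
        out.append(curve.rename(columns={"value": name}))
    return (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["step_minutes", "tau", name, "n_tracks"])
    )


# ---------------------------------------------------------------------------
# Speed heterogeneity
# ---------------------------------------------------------------------------

def instantaneous_speeds(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-step horizontal speed of every segment (µm per time step)."""
    rows = []
    for (sample, crop, track, branch), seg in cells.groupby(_SEGKEY, sort=True):
        seg = seg.sort_values("time", kind="mergesort")
        xy = seg[["pos_x", "pos_y"]].to_numpy(float)
        sp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        for t, s in zip(seg["time"].to_numpy()[:-1], sp):
            rows.append(
                {"sample": sample, "crop": crop, "track": track, "branch": branch,
                 "time": int(t), "speed": float(s)}
            )
    return pd.DataFrame(rows, columns=["sample", "crop", "track", "branch", "time", "speed"])


@dataclass(frozen=True)
class SpeedHeterogeneity:
    """Nested-regression comparison of speed ~ sample vs speed ~ sample + cell."""

    f_statistic: float
    p_value: float
    rss_reduction_percent: float
    rss_sample: float
    rss_sample_track: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"speed heterogeneity: F = {self.f_statistic:.3g}, p = {self.p_value:.3g}, "
            f"RSS reduced by {self.rss_reduction_percent:.1f}%"
        )


def speed_heterogeneity(speeds: pd.DataFrame) -> SpeedHeterogeneity:
    """Test for between-cell speed heterogeneity beyond sample effects.

    Instantaneous horizontal speed is regressed on sample id alone and then
    on sample id plus cell (unbranched segment) id, both categorical; the
    two nested linear models are compared by an F-test, and the percentage
    reduction in residual sum of squares is reported as the share of speed
    variability attributable to cell identity.
    """
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm

    df = speeds.copy()
    df["cell"] = (
        df["sample"].astype(str) + "/" + df["crop"].astype(str) + "/"
        + df["track"].astype(str) + "/" + df["branch"].astype(str)
    )
    if df["cell"].nunique() < 2:
        raise ValidationError("speed heterogeneity needs at least 2 cells")
    y = df["speed"].to_numpy(float)
    x1 = pd.get_dummies(df["sample"].astype(str), drop_first=True, dtype=float)
    x2 = pd.get_dummies(df["cell"], drop_first=True, dtype=float)
    m1 = sm.OLS(y, sm.add_constant(x1, has_constant="add")).fit()
    m2 = sm.OLS(y, sm.add_constant(pd.concat([x1, x2], axis=1), has_constant="add")).fit()
    rss1, rss2 = float(m1.ssr), float(m2.ssr)
    reduction = 100.0 * (rss1 - rss2) / rss1 if rss1 > 0 else 0.0
    if rss1 == 0.0 or rss2 == 0.0:
        return SpeedHeterogeneity(np.nan, np.nan, reduction, rss1, rss2)
    cmp_tab = anova_lm(m1, m2)
    return SpeedHeterogeneity(
        float(cmp_tab["F"].iloc[1]), float(cmp_tab["Pr(>F)"].iloc[1]), reduction, rss1, rss2
    )


# ---------------------------------------------------------------------------
# Tip attraction / repulsion
# ---------------------------------------------------------------------------

def exclude_near_edge(spots: pd.DataFrame, bounds_of, margin: float = EDGE_MARGIN_UM) -> pd.Series:
    """Boolean mask of spots to KEEP: lateral distance to every crop edge ≥ margin.

    *bounds_of* maps ``(sample, crop)`` → ``(xmin, xmax, ymin, ymax, ...)``
    (callable or mapping).  Exclusion is strict: a spot exactly *margin*
    from an edge is kept.  Raises :class:`ValidationError` when bounds are
    unavailable for a crop.
    """
    getter = bounds_of if callable(bounds_of) else lambda s, c: bounds_of[(s, c)]
    keep = np.ones(len(spots), dtype=bool)
    pos = spots[["pos_x", "pos_y"]].to_numpy(float)
    idx = np.arange(len(spots))
    for (sample, crop), grp in spots.reset_index(drop=True).groupby(["sample", "crop"], sort=False):
        try:
            b = getter(sample, crop)
        except KeyError as exc:
            raise ValidationError(
                f"no crop bounds for sample {sample!r} crop {crop!r}; supply bounds metadata "
                "or infer them from the data"
            ) from exc
        xmin, xmax, ymin, ymax = b[0], b[1], b[2], b[3]
        g = grp.index.to_numpy()
        edge_d = np.minimum.reduce(
            [pos[g, 0] - xmin, xmax - pos[g, 0], pos[g, 1] - ymin, ymax - pos[g, 1]]
        )
        keep[idx[g]] = edge_d >= margin
    return pd.Series(keep, index=spots.index)


def tip_directed_movement(context: pd.DataFrame, corrected: pd.DataFrame) -> pd.DataFrame:
    """Projection of next-step drift-corrected movement onto the tip direction.

    *context* carries raw positions with tip vectors (``tip_dx/dy/dz``,
    ``tip_distance``); *corrected* carries drift-corrected positions with
    the same keys.  For each spot that is not the last of its segment the
    returned table holds the initial (raw) tip distance ``d``, the signed
    projection ``m`` (µm; positive toward the tip), and the horizontal and
    3D magnitudes of the movement.  Spots with a zero tip vector are
    skipped with a warning.
    """
    key = _SEGKEY + ["time"]
    merged = context.merge(
        corrected[key + _COORDS].rename(columns={c: c + "_corr" for c in _COORDS}),
        on=key, how="inner", validate="one_to_one",
    )
    rows = []
    n_zero = 0
    for _, seg in merged.groupby(_SEGKEY, sort=True):
        seg = seg.sort_values("time", kind="mergesort")
        pc = seg[["pos_x_corr", "pos_y_corr", "pos_z_corr"]].to_numpy(float)
        move = np.diff(pc, axis=0)
        consecutive = np.diff(seg["time"].to_numpy(int)) == 1
        tip = seg[["tip_dx", "tip_dy", "tip_dz"]].to_numpy(float)[:-1]
        dist = seg["tip_distance"].to_numpy(float)[:-1]
        ok = (dist > 0) & consecutive
        n_zero += int((dist <= 0).sum())
        u = np.zeros_like(tip)
        u[ok] = tip[ok] / dist[ok, None]
        m = np.sum(move * u, axis=1)
        sub = seg.iloc[:-1]
        for r, (_, row) in enumerate(sub.iterrows()):
            if not ok[r]:
                continue
            rows.append(
                {
                    "sample": row["sample"], "crop": row["crop"], "track": row["track"],
                    "branch": row["branch"], "time": int(row["time"]),
                    "d": float(dist[r]), "m": float(m[r]),
                    "move_xy": float(np.hypot(move[r, 0], move[r, 1])),
                    "move_3d": float(np.linalg.norm(move[r])),
                }
            )
    if n_zero:
        logger.warning("%d spot(s) with zero tip vector skipped in projection", n_zero)
    return pd.DataFrame(
        rows, columns=["sample", "crop", "track", "branch", "time", "d", "m", "move_xy", "move_3d"]
    )


def attraction_repulsion_tests(moves: pd.DataFrame, split: float = DISTANCE_SPLIT_UM) -> pd.DataFrame:
    """Single-sample two-sided t-tests of tip-directed movement near vs far.

    Moves (already edge-excluded) are split at *split* µm of initial tip
    distance; each group's mean projected movement is tested against zero.
    Returns one row per group with ``n, mean_m, median_m,
    mean_abs_movement`` (horizontal) and the t statistic / p-value (NaN
    when n < 2).
    """
    rows = []
    groups = [(f"d<{split:g}", moves["d"] < split), (f"d>{split:g}", moves["d"] >= split)]
    for label, mask in groups:
        sub = moves[mask]
        rec = {
            "group": label,
            "n": len(sub),
            "mean_m": float(sub["m"].mean()) if len(sub) else np.nan,
            "median_m": float(sub["m"].median()) if len(sub) else np.nan,
            "mean_abs_movement": float(sub["move_xy"].mean()) if len(sub) else np.nan,
            "t": np.nan,
            "p": np.nan,
        }
        if len(sub) >= 2 and sub["m"].std(ddof=1) > 0:
            t, p = stats.ttest_1samp(sub["m"].to_numpy(float), 0.0)
            rec["t"], rec["p"] = float(t), float(p)
        rows.append(rec)
    return pd.DataFrame(rows)


def distance_trend_regression(
    moves: pd.DataFrame, threshold: float = REGRESSION_THRESHOLD_UM
) -> tuple[float, float]:
    """OLS of projected movement on initial tip distance beyond *threshold* µm.

    Tests whether the strength of attraction still varies with distance in
    the far field; returns ``(slope, p_value)``.
    """
    sub = moves[moves["d"] > threshold]
    if len(sub) < 3:
        raise ValidationError(f"need ≥3 moves beyond {threshold} µm, have {len(sub)}")
    d = sub["d"].to_numpy(float)
    if np.ptp(d) == 0:
        raise ValidationError("degenerate regression: all distances equal")
    res = stats.linregress(d, sub["m"].to_numpy(float))
    return float(res.slope), float(res.pvalue)
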