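"""Tip-relative geometry: nearest tip point, tip-end track, attachment flags.

For every tracked cell at every time step the position *prior to drift
correction* is compared against the cloud of points representing the
nearest ureteric tip volume at that time step; the cell-to-tip vector and
distance drive the attraction/repulsion statistics and the distance model
downstream.  The vertical-angle rule classifies a cell as horizontally
located relative to its tip when the cell→tip vector makes an angle of
less than 45° with the horizontal plane, i.e. ``|dz| < hypot(dx, dy)``
(strict: the 45° boundary itself is *not* horizontal); attachment can be
obscured by poor z resolution when a cell sits directly above or below the
tip surface, so attachment proportions are assessed on the horizontal
subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MissingTipError, ValidationError
from .io import Dataset

logger = logging.getLogger("capmotion.tipgeom")

_COORDS = ["pos_x", "pos_y", "pos_z"]


def nearest_tip_point(cell, cloud) -> tuple[np.ndarray, float]:
    """Vector (cell→tip point) and distance to the nearest tip-cloud point.

    Exact nearest neighbour by Euclidean distance; raises
    :class:`MissingTipError` on an empty cloud.
    """
    cloud = np.asarray(cloud, dtype=float).reshape(-1, 3)
    if len(cloud) == 0:
        raise MissingTipError("empty tip cloud")
    cell = np.asarray(cell, dtype=float)
    if len(cloud) > 32:
        dist, idx = cKDTree(cloud).query(cell)
    else:
        d = np.linalg.norm(cloud - cell, axis=1)
        idx = int(np.argmin(d))
        dist = d[idx]
    return cloud[idx] - cell, float(dist)


def classify_horizontal(vector) -> bool:
    """True when the vector's vertical angle is strictly below 45°.

    A zero vector (cell coincides with a tip point, a distance-0 contact)
    is classified horizontal and logged.
    """
    dx, dy, dz = (float(v) for v in np.asarray(vector, dtype=float))
    if dx == 0.0 and dy == 0.0 and dz == 0.0:
        logger.warning("zero tip vector classified as horizontal (distance-0 contact)")
        return True
    return bool(abs(dz) < np.hypot(dx, dy))


def nearest_tip_end(cell, tip_positions: dict) -> tuple[object, float]:
    """Nearest tip-end track at one time step.

    *tip_positions* maps tip track id → (x, y, z).  Ties are broken in
    favour of the lowest tip track id; raises :class:`MissingTipError` if
    no tip track is defined at this time step.
    """
    if not tip_positions:
        raise MissingTipError("no tip end track defined at this time step")
    cell = np.asarray(cell, dtype=float)
    best_id, best_d = None, np.inf
    for tid in sorted(tip_positions, key=str):
        d = float(np.linalg.norm(np.asarray(tip_positions[tid], dtype=float) - cell))
        if d < best_d:
            best_id, best_d = tid, d
    return best_id, best_d


def segment_key(row) -> str:
    """Canonical unbranched-segment identifier used in annotation tables."""
    return f"{row['sample']}/{row['crop']}/{row['track']}/{row['branch']}"


def map_attachment(cells: pd.DataFrame, intervals: pd.DataFrame, annotated_tracks) -> pd.Series:
    """Per-spot attachment state: ``attached`` / ``free`` / ``unannotated``.

    *intervals* has columns ``track, first, last`` (inclusive time-step
    ranges) whose track ids must all appear in *annotated_tracks*; spots on
    annotated segments outside every interval are ``free``, spots on
    unannotated segments are ``unannotated``.
    """
    annotated = set(annotated_tracks)
    unknown = set(intervals["track"]) - annotated
    if unknown:
        raise ValidationError(
            f"attachment interval(s) reference track(s) not in the annotation set: {sorted(unknown)[:5]}"
        )
    keys = cells.apply(segment_key, axis=1) if len(cells) else pd.Series(dtype=object)
    known_keys = set(keys)
    missing = annotated - known_keys
    if missing:
        raise ValidationError(
            f"annotated track(s) absent from the cell table: {sorted(missing)[:5]}"
        )
    state = pd.Series("unannotated", index=cells.index, dtype=object)
    ann_mask = keys.isin(annotated)
    state[ann_mask] = "free"
    by_track: dict = {}
    for _, iv in intervals.iterrows():
        by_track.setdefault(iv["track"], []).append((int(iv["first"]), int(iv["last"])))
    for track, ivs in by_track.items():
        on_track = keys == track
        span_lo, span_hi = cells.loc[on_track, "time"].min(), cells.loc[on_track, "time"].max()
        for lo, hi in ivs:
            if lo > hi or lo < span_lo or hi > span_hi:
                raise ValidationError(
                    f"interval [{lo}, {hi}] outside the span [{span_lo}, {span_hi}] of track {track!r}"
                )
            state[on_track & cells["time"].between(lo, hi)] = "attached"
    return state


def compute_tip_context(dataset: Dataset, include_attachment: bool = True) -> pd.DataFrame:
    """Tip context for every cell spot in a dataset.

    Returns the cell table extended with ``tip_dx, tip_dy, tip_dz`` (vector
    cell→nearest tip point, µm), ``tip_distance``, ``is_horizontal``,
    ``nearest_tip_track``, ``tip_track_distance``, and (when annotations
    exist) ``attachment``.  All geometry uses raw, pre-drift-correction
    positions.
    """
    cells = dataset.cells.reset_index(drop=True)
    n = len(cells)
    out = cells.copy()
    vec = np.full((n, 3), np.nan)
    dist = np.full(n, np.nan)
    tip_id = np.full(n, None, dtype=object)
    tip_d = np.full(n, np.nan)

    clouds = {k: g for k, g in dataset.tip_clouds.groupby(["crop", "time"], sort=False)}
    ends = {k: g for k, g in dataset.tip_ends.groupby(["crop", "time"], sort=False)}
    for (crop, t), grp in cells.groupby(["crop", "time"], sort=False):
        if (crop, t) not in clouds:
            raise MissingTipError(f"no tip cloud for crop {crop!r} at time step {t}")
        cloud = clouds[(crop, t)][_COORDS].to_numpy(float)
        pos = grp[_COORDS].to_numpy(float)
        tree = cKDTree(cloud)
        d, idx = tree.query(pos)
        vec[grp.index] = cloud[idx] - pos
        dist[grp.index] = d
        if (crop, t) in ends:
            etab = ends[(crop, t)]
            tip_positions = {
                row["tip_track"]: row[_COORDS].to_numpy(float) for _, row in etab.iterrows()
            }
            for ridx, p in zip(grp.index, pos):
                tid, td = nearest_tip_end(p, tip_positions)
                tip_id[ridx], tip_d[ridx] = tid, td
    out["tip_dx"], out["tip_dy"], out["tip_dz"] = vec[:, 0], vec[:, 1], vec[:, 2]
    out["tip_distance"] = dist
    with np.errstate(invalid="ignore"):
        planar = np.hypot(vec[:, 0], vec[:, 1])
        out["is_horizontal"] = (np.abs(vec[:, 2]) < planar) | (dist == 0.0)
    out["nearest_tip_track"] = tip_id
    out["tip_track_distance"] = tip_d
    if include_attachment and (len(dataset.attachments) or dataset.annotated_tracks):
        out["attachment"] = map_attachment(
            cells, dataset.attachments, dataset.annotated_tracks
        ).to_numpy()
    return out
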