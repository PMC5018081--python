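"""Drift correction against moving ureteric tips.

Imaged kidney explants contain several tips growing in different
directions, and cap cells ride along with "their" tip as well as with any
bulk movement of the sample.  To isolate intrinsic cell movement, each
cell's per-interval movement has subtracted from it a weighted average of
the tip-end-track movements over the same interval, with weights
proportional to the inverse square distance from the cell to each tip at
the interval's start step.  A cell sitting on one tip therefore follows
that tip almost exclusively (its weight → 1 as distance → 0), while cells
between tips blend references smoothly; uniform bulk movement is carried
through the weighted average and removed exactly.

Correction applies to horizontal movement only — the z series is kept raw.
Corrected positions retain the original position of each segment at its
first time step and accumulate corrected movements from there.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CorrectionError

logger = logging.getLogger("capmotion.drift")

_COORDS = ["pos_x", "pos_y", "pos_z"]

#: distances below this (µm) count as coincident with a tip
EPSILON = 1e-9


def tip_weights(cell, tip_positions: dict, eps: float = EPSILON) -> dict:
    """Inverse-square-distance weights over tip tracks, normalised to 1.

    *tip_positions* maps tip track id → (x, y, z) at the interval's start
    step.  A cell within *eps* of a tip takes weight 1 on that tip (the
    1/d² limit); raises :class:`CorrectionError` when no tip is given.
    """
    if not tip_positions:
        raise CorrectionError("no tip track available for weighting")
    cell = np.asarray(cell, dtype=float)
    ids = sorted(tip_positions, key=str)
    d = np.array(
        [np.linalg.norm(np.asarray(tip_positions[t], dtype=float) - cell) for t in ids]
    )
    if (d < eps).any():
        w = np.zeros_like(d)
        w[int(np.argmin(d))] = 1.0  # coincident tip takes the full weight
    else:
        w = 1.0 / d**2
        w = w / w.sum()
    return dict(zip(ids, w))


def corrected_movement(cell_move, tip_moves: dict, weights: dict) -> np.ndarray:
    """Cell movement minus the weighted average tip movement (horizontal only).

    *cell_move* is the raw (dx, dy, dz) over one interval; *tip_moves*
    maps tip track id → that tip's (dx, dy[, dz]) movement.  The returned
    vector keeps the raw dz.
    """
    cell_move = np.asarray(cell_move, dtype=float)
    drift = np.zeros(2)
    for tid, w in weights.items():
        mv = np.asarray(tip_moves[tid], dtype=float)
        drift += w * mv[:2]
    return np.array([cell_move[0] - drift[0], cell_move[1] - drift[1], cell_move[2]])


def _tip_tables(tip_ends: pd.DataFrame, crop) -> dict:
    """time step -> {tip_track: position} for one crop."""
    sub = tip_ends[tip_ends["crop"] == crop]
    table: dict = {}
    for _, row in sub.iterrows():
        table.setdefault(int(row["time"]), {})[row["tip_track"]] = row[_COORDS].to_numpy(float)
    return table


def correct_segment(segment: pd.DataFrame, tip_by_time: dict) -> pd.DataFrame:
    """Drift-correct one unbranched segment.

    *segment* rows must be consecutive time steps of a single cell;
    *tip_by_time* maps time step → {tip_track: position} (from
    :func:`_tip_tables`).  Tips missing at either end of an interval are
    dropped from that interval's weighting (weights renormalised over the
    rest); an interval with no tip present at both ends raises
    :class:`CorrectionError`.
    """
    seg = segment.sort_values("time", kind="mergesort").reset_index(drop=True)
    pos = seg[_COORDS].to_numpy(float)
    times = seg["time"].to_numpy(int)
    corrected = pos.copy()
    for i in range(len(seg) - 1):
        t0, t1 = int(times[i]), int(times[i + 1])
        tips0 = tip_by_time.get(t0, {})
        tips1 = tip_by_time.get(t1, {})
        usable = {tid: p for tid, p in tips0.items() if tid in tips1}
        if not usable:
            raise CorrectionError(f"no tip track defined at both t={t0} and t={t1}")
        w = tip_weights(pos[i], usable)
        moves = {tid: tips1[tid] - tips0[tid] for tid in usable}
        dm = corrected_movement(pos[i + 1] - pos[i], moves, w)
        corrected[i + 1, :2] = corrected[i, :2] + dm[:2]
    corrected[:, 2] = pos[:, 2]  # z stays raw
    out = seg.copy()
    out["pos_x"], out["pos_y"], out["pos_z"] = corrected[:, 0], corrected[:, 1], corrected[:, 2]
    return out


def correct_dataset(cells: pd.DataFrame, tip_ends: pd.DataFrame) -> pd.DataFrame:
    """Drift-correct every unbranched segment of a resolved cell table.

    Returns a table mirroring the input schema with corrected ``pos_x`` /
    ``pos_y`` and raw ``pos_z``.  Each daughter segment anchors at its own
    raw first position.  Crops are corrected independently — a cell never
    weights tips from another crop.
    """
    parts = []
    for crop, crop_cells in cells.groupby("crop", sort=False):
        tip_by_time = _tip_tables(tip_ends, crop)
        for _, seg in crop_cells.groupby(["sample", "track", "branch"], sort=False):
            parts.append(correct_segment(seg, tip_by_time))
    if not parts:
        return cells.iloc[0:0].copy()
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(
        ["sample", "crop", "track", "branch", "time"], kind="mergesort"
    ).reset_index(drop=True)
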