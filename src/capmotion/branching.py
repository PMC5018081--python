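"""Branch-point identification and splitting of branched tracks.

Tracking software that allows mitosis in a track exports all spots of the
lineage under one track id without distinguishing daughter cells.  This
module re-associates cell positions across consecutive time steps within
each branched track under the degree constraints of a lineage (each
position has at most one predecessor and at most two successors), then
splits the lineage into unbranched segments at the identified branch
points.

The per-frame-pair association is the lexicographic optimum over

1. number of unmatched endpoints (positions at ``t`` with no successor plus
   positions at ``t+1`` with no predecessor) — minimised first, because in
   a connected lineage every spot should link;
2. number of bifurcations (positions at ``t`` matched to two successors);
3. total Euclidean distance between matched positions.

With tier 1 at its minimum the bifurcation count is already forced, so the
effective objective is "fewest terminations and bifurcations, then least
total distance".  Each frame pair is solved as a min-cost assignment with
every parent duplicated (allowing up to two children) and dummy nodes
priced so that an unmatched endpoint outweighs any bifurcation, which in
turn outweighs any sum of distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger("capmotion.branching")

_COORDS = ["pos_x", "pos_y", "pos_z"]


@dataclass(frozen=True)
class FrameMatching:
    """Association between positions at ``t`` and positions at ``t+1``.

    ``pairs`` holds ``(parent_index, child_index)`` tuples referring to the
    input orders of :func:`match_frames`.
    """

    n_prev: int
    n_next: int
    pairs: tuple = ()

    @property
    def terminations(self) -> int:
        matched = {i for i, _ in self.pairs}
        return self.n_prev - len(matched)

    @property
    def bifurcations(self) -> int:
        counts = np.bincount([i for i, _ in self.pairs], minlength=self.n_prev)
        return int((counts == 2).sum()) if len(self.pairs) else 0

    @property
    def starts(self) -> int:
        return self.n_next - len(self.pairs)

    def total_distance(self, prev: np.ndarray, next_: np.ndarray) -> float:
        return float(
            sum(np.linalg.norm(np.asarray(prev)[i] - np.asarray(next_)[j]) for i, j in self.pairs)
        )


def match_frames(prev, next_) -> FrameMatching:
    """Match positions at ``t`` to positions at ``t+1``.

    Parameters are arrays of shape ``(n, 3)`` (either may be empty).  Each
    child gets at most one parent and each parent at most two children; the
    matching minimises, lexicographically, (unmatched endpoints,
    bifurcations, total Euclidean distance).  Deterministic for fixed input
    order.
    """
    prev = np.asarray(prev, dtype=float).reshape(-1, 3)
    next_ = np.asarray(next_, dtype=float).reshape(-1, 3)
    n, m = len(prev), len(next_)
    if n == 0 or m == 0:
        return FrameMatching(n, m, ())
    dist = np.linalg.norm(prev[:, None, :] - next_[None, :, :], axis=2)
    # penalty tiers: unmatched endpoint >> bifurcation >> any distance sum
    p_bif = dist.sum() + 1.0
    p_end = (2 * n + m + 1) * p_bif + 1.0
    # rows: parent first copies [0, n), parent second copies [n, 2n), dummy parents [2n, 2n+m)
    # cols: children [0, m), dummy children [m, m+2n)
    cost = np.zeros((2 * n + m, m + 2 * n))
    cost[0:n, 0:m] = dist
    cost[n : 2 * n, 0:m] = dist + p_bif
    cost[2 * n : 2 * n + m, 0:m] = p_end  # child left unmatched (a track start)
    cost[0:n, m:] = p_end  # parent left without any child (a termination)
    cost[n : 2 * n, m:] = 0.0  # unused second copy is free
    cost[2 * n :, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for r, c in zip(rows, cols):
        if c < m and r < 2 * n:
            pairs.append((r % n, int(c)))
    pairs.sort()
    return FrameMatching(n, m, tuple(pairs))


@dataclass
class UnbranchedSegment:
    """Maximal stretch of a track with exactly one cell per consecutive frame."""

    segment_id: str
    spots: pd.DataFrame  # rows in time order, one per time step
    parent_segment_id: str | None = None

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class TrackResolution:
    segments: list = field(default_factory=list)
    branch_points: list = field(default_factory=list)  # (time_step, (x, y, z))


def resolve_track(track: pd.DataFrame) -> TrackResolution:
    """Split one (possibly branched) track into unbranched segments.

    *track* is a DataFrame with at least ``time, pos_x, pos_y, pos_z``;
    all its rows must belong to a single track.  Spots within each frame
    are canonically ordered by coordinates before matching, so the result
    does not depend on input row order.

    A position with two successors is a branch point: the parent segment
    ends there and two child segments begin at the next step, carrying a
    ``parent_segment_id`` link.  A frame with no spots inside the track's
    span splits the track into independent parts (logged).
    """
    track = track.sort_values(["time"] + _COORDS, kind="mergesort").reset_index(drop=True)
    if not len(track):
        return TrackResolution()
    time_arr = track["time"].to_numpy(int)
    pos = track[_COORDS].to_numpy(float)
    times, starts_idx = np.unique(time_arr, return_index=True)
    times = [int(t) for t in times]
    bounds = list(starts_idx) + [len(track)]
    frame_rows = {t: np.arange(bounds[k], bounds[k + 1]) for k, t in enumerate(times)}
    n_gaps = (times[-1] - times[0] + 1) - len(times)
    if n_gaps:
        logger.warning("track has %d empty frame(s) inside its span; splitting", n_gaps)
    # forest over (time, row position within frame)
    children: dict[tuple, list] = {}
    parent: dict[tuple, tuple] = {}
    for t0, t1 in zip(times[:-1], times[1:]):
        if t1 != t0 + 1:
            continue  # gap: no association across it
        fm = match_frames(pos[frame_rows[t0]], pos[frame_rows[t1]])
        for i, j in fm.pairs:
            children.setdefault((t0, i), []).append((t1, j))
            parent[(t1, j)] = (t0, i)
    all_nodes = [(t, i) for t in times for i in range(len(frame_rows[t]))]
    roots = [nd for nd in all_nodes if nd not in parent]
    branch_nodes = [nd for nd in all_nodes if len(children.get(nd, [])) == 2]
    branch_points = [
        (int(t), tuple(pos[frame_rows[t][i]])) for t, i in branch_nodes
    ]
    # segment start nodes: roots plus children of branch nodes
    starts = list(roots)
    for nd in branch_nodes:
        starts.extend(children[nd])
    starts.sort()
    seg_of_start = {nd: str(k) for k, nd in enumerate(starts)}
    segments = []
    for nd in starts:
        seg_id = seg_of_start[nd]
        par = parent.get(nd)
        parent_seg = None
        if par is not None and len(children.get(par, [])) == 2:
            # walk back to the start of the parent's segment
            walk = par
            while walk in parent and len(children[parent[walk]]) != 2:
                walk = parent[walk]
            parent_seg = seg_of_start.get(walk)
        chain = [nd]
        cur = nd
        while len(children.get(cur, [])) == 1:
            cur = children[cur][0]
            chain.append(cur)
        rows = track.iloc[[frame_rows[t][i] for t, i in chain]].reset_index(drop=True)
        segments.append(UnbranchedSegment(seg_id, rows, parent_seg))
    return TrackResolution(segments, sorted(branch_points))


def resolve_dataset(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign branch ids to every spot of every track in a cell table.

    Returns ``(cells_with_branch, parent_links)`` where the first mirrors
    the input with the ``branch`` column set to the resolved segment id and
    the second has columns ``sample, crop, track, branch, parent_branch``.
    Every input spot appears in exactly one segment.
    """
    out_parts, links = [], []
    for (sample, crop, track_id), grp in cells.groupby(["sample", "crop", "track"], sort=True):
        res = resolve_track(grp)
        for seg in res.segments:
            rows = seg.spots.copy()
            rows["branch"] = seg.segment_id
            out_parts.append(rows)
            links.append(
                {
                    "sample": sample,
                    "crop": crop,
                    "track": track_id,
                    "branch": seg.segment_id,
                    "parent_branch": seg.parent_segment_id,
                }
            )
    resolved = (
        pd.concat(out_parts, ignore_index=True)
        if out_parts
        else cells.iloc[0:0].copy()
    )
    resolved = resolved.sort_values(
        ["sample", "crop", "track", "branch", "time"], kind="mergesort"
    ).reset_index(drop=True)
    return resolved, pd.DataFrame(links, columns=["sample", "crop", "track", "branch", "parent_branch"])
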