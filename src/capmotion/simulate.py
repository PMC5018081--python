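"""Synthetic track data with the statistical structure the analysis assumes.

The generator emulates a cropped live-imaging field of a developing kidney:
several ureteric tips drift through the field, and cap cells around them
move with (i) tip-coupled drift — the inverse-square-distance weighted
average of tip movements, exactly the reference model the drift correction
assumes; (ii) a distance-dependent radial convection ``v(d) = D·k(d)``
along the cell→tip axis (positive k pushes away from the tip); and (iii)
undirected noise.  Cells divide with a fixed per-step probability, and the
exported z coordinate carries extra independent measurement noise
("z-jitter") reproducing the poor axial resolution of confocal stacks.

The radial coordinate of each cell relative to its nearest tip centre is
updated as a reflected 1-D convection-diffusion step
``Δd = D·k(d) + √(2D)·ξ`` while the angular position diffuses over the
sphere, so with a single static tip the surface distance follows exactly
the 1-D steady state ``y(d) ∝ exp(∫₀^d k)`` that the distance model fits.
Tip volumes are emitted as deterministic point clouds (Fibonacci sphere
plus interior shell), tip-end tracks as the tip centres.

Everything is reproducible: one scenario + seed gives byte-identical CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import branching
from .io import Dataset
from .model import KProfile, sample_steady_state
from .tipgeom import segment_key

_COORDS = ["pos_x", "pos_y", "pos_z"]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit directions (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterisation of the simulator.

    Defaults describe one 20-minute-interval sample: a 300×300×80 µm crop
    with 3 tips of radius 8 µm drifting at 0.5 µm/step, 200 cells whose
    radial motion follows the default attraction/repulsion profile
    (repulsive at the tip surface, attractive in the far field) with
    diffusion D = 4 µm²/step, tangential/axial noise of 2 µm per axis per
    step, ~0.2% division probability per cell-step, and 2 µm z-jitter.
    """

    n_tips: int = 3
    tip_speed: float = 0.5           # µm/step, horizontal drift of each tip
    tip_radius: float = 8.0          # µm
    tip_cloud_points: int = 120      # points per tip volume per frame
    n_cells: int = 200
    diffusion: float = 4.0           # D, µm²/step (radial noise sd = sqrt(2 D))
    sigma: float = 2.0               # tangential noise sd, µm per axis per step
    profile: KProfile = field(default_factory=lambda: KProfile(0.0, 14.95, 0.293, -0.098))
    division_prob: float = 0.002     # per cell per step
    z_jitter_sd: float = 2.0         # µm measurement noise on exported z
    step_minutes: int = 20
    n_steps: int = 70                # number of frames
    bounds: tuple = (0.0, 300.0, 0.0, 300.0, 0.0, 80.0)
    d_init_max: float = 40.0         # µm, initial surface-distance range
    attach_distance: float = 2.0     # µm of surface within which a cell is "attached"
    annotated_fraction: float = 1.0  # fraction of segments annotated for attachment
    sample_id: str = "s1"
    crop_id: str = "c1"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tips, self.n_cells, self.n_steps) < 1:
            raise ValueError("n_tips, n_cells and n_steps must be positive")
        xm, xM, ym, yM, zm, zM = self.bounds
        if not (xm < xM and ym < yM and zm < zM):
            raise ValueError("degenerate crop bounds")


@dataclass
class GroundTruthLedger:
    """Replayable record of what the simulator actually did.

    ``truth`` has one row per cell instance per frame with the true
    (jitter-free) position, surface distance, assigned tip, attachment
    flag and the intrinsic (drift-free) displacement to the next frame.
    """

    truth: pd.DataFrame
    divisions: pd.DataFrame           # time, parent, child
    tip_centers: pd.DataFrame         # tip, time, x, y, z
    n_reflections: int = 0

    @property
    def n_spots(self) -> int:
        return len(self.truth)

    @property
    def n_tracks(self) -> int:
        return self.truth["track"].nunique()


def simulate(scenario: SyntheticScenario) -> tuple[Dataset, GroundTruthLedger]:
    """Run the forward model and emit a schema-compliant dataset."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    xm, xM, ym, yM, zm, zM = sc.bounds
    center = np.array([(xm + xM) / 2, (ym + yM) / 2, (zm + zM) / 2])

    # --- tips: centres spread around the crop middle, constant drift
    if sc.n_tips == 1:
        tip0 = center[None, :].copy()
    else:
        ang = 2 * np.pi * np.arange(sc.n_tips) / sc.n_tips
        spread = 0.25 * min(xM - xm, yM - ym)
        tip0 = center[None, :] + spread * np.column_stack(
            [np.cos(ang), np.sin(ang), np.zeros(sc.n_tips)]
        )
    vel_ang = rng.uniform(0, 2 * np.pi, sc.n_tips)
    tip_vel = sc.tip_speed * np.column_stack(
        [np.cos(vel_ang), np.sin(vel_ang), np.zeros(sc.n_tips)]
    )

    def tip_centers_at(t: int) -> np.ndarray:
        return tip0 + t * tip_vel

    # --- cells: seeded around tips at steady-state surface distances
    n0 = sc.n_cells
    d0 = sample_steady_state(sc.profile, n0, sc.d_init_max, seed=rng.integers(2**31))
    dirs = rng.normal(size=(n0, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    assigned = np.arange(n0) % sc.n_tips
    radius = sc.tip_radius
    pos = tip_centers_at(0)[assigned] + (d0 + radius)[:, None] * dirs

    next_instance = n0
    lineage = {i: i for i in range(n0)}  # instance -> lineage root (track id)
    alive = list(range(n0))
    positions = {i: pos[i] for i in alive}

    truth_rows: list = []
    intr_rows: list = []  # intrinsic (drift-free) displacement per step
    div_rows: list = []
    n_reflections = 0
    sqrt2d = np.sqrt(2.0 * sc.diffusion)

    for t in range(sc.n_steps):
        c_now, c_next = tip_centers_at(t), tip_centers_at(t + 1)
        tip_moves = c_next - c_now
        new_positions: dict = {}
        for i in alive:
            p = positions[i]
            dvec = p[None, :] - c_now
            dists = np.linalg.norm(dvec, axis=1)
            j = int(np.argmin(dists))
            r = dists[j]
            d_surf = max(0.0, r - radius)
            # record the current frame
            truth_rows.append((i, t, p[0], p[1], p[2], d_surf, j))
            if t == sc.n_steps - 1:
                continue
            # inverse-square drift weights over tip centres
            w = 1.0 / np.maximum(dists, 1e-9) ** 2
            w /= w.sum()
            drift = (w[:, None] * tip_moves).sum(axis=0)
            drift[2] = 0.0
            # 1-D reflected convection-diffusion step on the surface distance
            d_new = d_surf + sc.diffusion * sc.profile.k(d_surf) + sqrt2d * rng.normal()
            if d_new < 0:
                d_new = -d_new
                n_reflections += 1
            # angular diffusion on the sphere around the assigned tip
            u = dvec[j] / r if r > 0 else np.array([1.0, 0.0, 0.0])
            tau = rng.normal(scale=sc.sigma, size=3)
            tau -= (tau @ u) * u  # tangential component only
            u_new = r * u + tau
            u_new /= np.linalg.norm(u_new)
            p_new = c_now[j] + (radius + d_new) * u_new + drift
            # keep inside the crop (reflect); z additionally clamped to bounds
            for ax, (lo, hi) in enumerate([(xm, xM), (ym, yM), (zm, zM)]):
                if p_new[ax] < lo:
                    p_new[ax] = 2 * lo - p_new[ax]
                    n_reflections += 1
                elif p_new[ax] > hi:
                    p_new[ax] = 2 * hi - p_new[ax]
                    n_reflections += 1
            intr = p_new - p - drift
            intr_rows.append((i, t, intr[0], intr[1], intr[2]))
            new_positions[i] = p_new
        if t == sc.n_steps - 1:
            break
        # divisions: duplicate with a small offset, same lineage track id
        for i in list(new_positions):
            if rng.random() < sc.division_prob:
                child = next_instance
                next_instance += 1
                off = rng.normal(size=3)
                off *= 0.75 / np.linalg.norm(off)
                new_positions[child] = new_positions[i] + off
                lineage[child] = lineage[i]
                div_rows.append((t + 1, i, child))
        alive = sorted(new_positions)
        positions = new_positions

    truth = pd.DataFrame(truth_rows, columns=["cell", "time", "x", "y", "z", "d_surf", "tip"])
    intr = pd.DataFrame(intr_rows, columns=["cell", "time", "intr_dx", "intr_dy", "intr_dz"])
    truth = truth.merge(intr, on=["cell", "time"], how="left")
    truth["track"] = truth["cell"].map(lineage)
    truth["attached"] = truth["d_surf"] < sc.attach_distance

    # --- emitted tables ------------------------------------------------
    cells = pd.DataFrame(
        {
            "sample": sc.sample_id,
            "crop": sc.crop_id,
            "track": "t" + truth["track"].astype(str),
            # placeholder branch ids: unique per concurrent cell instance so the
            # spot key stays unique, but carrying no lineage structure (the
            # acquisition export does not distinguish daughters either)
            "branch": "u" + truth["cell"].astype(str),
            "time": truth["time"].astype(int),
            "pos_x": truth["x"],
            "pos_y": truth["y"],
            "pos_z": truth["z"] + rng.normal(scale=sc.z_jitter_sd, size=len(truth)),
        }
    )
    cells = cells.sort_values(["track", "branch", "time"], kind="mergesort").reset_index(drop=True)

    sphere = _fibonacci_sphere(max(12, sc.tip_cloud_points * 2 // 3))
    inner = _fibonacci_sphere(max(4, sc.tip_cloud_points - len(sphere)))
    cloud_unit = np.vstack([sphere, 0.6 * inner])
    cloud_rows = []
    for t in range(sc.n_steps):
        for j, c in enumerate(tip_centers_at(t)):
            pts = c + sc.tip_radius * cloud_unit
            for p in pts:
                cloud_rows.append((sc.crop_id, t, p[0], p[1], p[2]))
    tip_clouds = pd.DataFrame(cloud_rows, columns=["crop", "time"] + _COORDS)

    end_rows = []
    for t in range(sc.n_steps):
        for j, c in enumerate(tip_centers_at(t)):
            end_rows.append((sc.crop_id, f"tip{j}", t, c[0], c[1], c[2]))
    tip_ends = pd.DataFrame(end_rows, columns=["crop", "tip_track", "time"] + _COORDS)

    tip_centers = pd.DataFrame(
        [
            (f"tip{j}", t, *c)
            for t in range(sc.n_steps)
            for j, c in enumerate(tip_centers_at(t))
        ],
        columns=["tip", "time", "x", "y", "z"],
    )
    divisions = pd.DataFrame(div_rows, columns=["time", "parent", "child"])
    ledger = GroundTruthLedger(truth, divisions, tip_centers, n_reflections)

    # --- attachment annotation on resolved segments ---------------------
    resolved, _ = branching.resolve_dataset(cells)
    att_intervals, annotated = _attachment_annotation(sc, rng, resolved, truth)

    metadata = {
        "step_minutes": {sc.sample_id: sc.step_minutes},
        "crop_bounds": {(sc.sample_id, sc.crop_id): tuple(map(float, sc.bounds))},
    }
    dataset = Dataset(cells, tip_clouds, tip_ends, att_intervals, annotated, metadata)
    dataset.validate()
    return dataset, ledger


def _attachment_annotation(sc, rng, resolved: pd.DataFrame, truth: pd.DataFrame):
    """Map true attachment runs onto resolved segment keys."""
    # true attached flag keyed by (time, rounded true-ish position) is not
    # robust under z-jitter, so match on (track, time, x, y) which survive
    # export unchanged
    att_map = {
        (f"t{r.track}", int(r.time), round(r.x, 6), round(r.y, 6)): bool(r.attached)
        for r in truth.itertuples()
    }
    intervals, annotated = [], []
    for _, seg in resolved.groupby(["sample", "crop", "track", "branch"], sort=True):
        seg = seg.sort_values("time", kind="mergesort")
        key = segment_key(seg.iloc[0])
        if rng.random() >= sc.annotated_fraction:
            continue
        annotated.append(key)
        flags = [
            att_map.get((r.track, int(r.time), round(r.pos_x, 6), round(r.pos_y, 6)), False)
            for r in seg.itertuples()
        ]
        times = seg["time"].to_numpy(int)
        start = None
        for f, t in zip(flags + [False], list(times) + [times[-1] + 1]):
            if f and start is None:
                start = t
            elif not f and start is not None:
                intervals.append({"track": key, "first": int(start), "last": int(t - 1)})
                start = None
    return pd.DataFrame(intervals, columns=["track", "first", "last"]), annotated


def make_division_fixture(
    n_frames: int, branch_step: int, divergence: float = 2.0, coincident: bool = False
) -> pd.DataFrame:
    """Small branched-track fixture with a known branch point.

    One cell moves +1 µm/step in x; at *branch_step* it divides and the two
    daughters separate by ±*divergence* µm/step in y (or stay coincident
    when *coincident*).  Returns a cell table (single track, placeholder
    branch ids) whose ground-truth branch point is at *branch_step*.
    """
    if not 0 < branch_step < n_frames - 1:
        raise ValueError("need 0 < branch_step < n_frames - 1")
    rows = []
    for t in range(n_frames):
        if t <= branch_step:
            rows.append(("s1", "c1", "t0", "u0", t, float(t), 0.0, 0.0))
        else:
            dy = 0.0 if coincident else divergence * (t - branch_step)
            rows.append(("s1", "c1", "t0", "u0", t, float(t), dy, 0.0))
            rows.append(("s1", "c1", "t0", "u1", t, float(t), -dy, 0.0))
    return pd.DataFrame(
        rows, columns=["sample", "crop", "track", "branch", "time", "pos_x", "pos_y", "pos_z"]
    )


def two_step_scenarios(seed: int = 0) -> tuple[SyntheticScenario, SyntheticScenario]:
    """A matched pair of scenarios at 15- and 20-minute steps (two samples)."""
    base = SyntheticScenario(seed=seed)
    s15 = replace(base, step_minutes=15, sample_id="s2", crop_id="c2", seed=seed + 1)
    return base, s15
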