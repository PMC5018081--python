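# Methods

This note documents the models and procedures implemented in `capmotion`,
the assumptions behind them, the numerical choices made where the design
was genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Data model

The atomic record is a *spot*: one object (a cell, or one point of a tip
volume) at one time step, with physical coordinates in µm.  Time is an
integer step index; the step length (15 or 20 minutes) is per-sample
metadata, and all statistics are per-step quantities — lags of τ steps
mean different wall-clock intervals across step-length groups, so curves
are never pooled across groups.  A sample may be partitioned into crops;
crops are analysed independently (a cell never references tips of another
crop).  Crop bounds come from metadata when declared and otherwise from
the bounding box of all spots and tip points in the crop, since the edge
exclusion below needs bounds even when the acquisition did not record
them.

## Branch resolution

Tracking software that permits mitosis in a track exports the whole
lineage under one track id without identifying daughters.  Positions at
consecutive time steps are re-associated under lineage degree constraints
(each position ≤1 predecessor, ≤2 successors), optimising
lexicographically:

1. unmatched endpoints (positions without successor plus positions
   without predecessor) — minimised first.  In a connected lineage every
   spot should link; treating an unmatched appearing position as a defect
   on par with a termination is what makes a division (one position with
   two successors) preferable to leaving a daughter unlinked.
2. bifurcations — given tier 1 at its minimum the bifurcation count is
   already forced, so this tier only breaks pathological ties.
3. total Euclidean distance between matched positions.

Each consecutive frame pair is solved independently as a min-cost
assignment (`scipy.optimize.linear_sum_assignment`): every parent is
duplicated (two child slots, the second priced with a bifurcation
penalty) and dummy nodes absorb unmatched endpoints at a penalty chosen
larger than any achievable sum of lower-tier costs, which encodes the
lexicographic objective in a single cost matrix.  A global multi-frame
optimisation was considered and rejected: per-pair optimisation matches
how the association is described operationally, is exactly testable
against brute-force enumeration, and is O(frames).  Gap closing is
deliberately absent — a cell missing at t+1 but present at t+2 starts a
new segment; an empty frame inside a track's span splits the track, with
a warning.  Spots within a frame are canonically ordered by coordinates
before matching, so results are invariant to input row order; remaining
ties between exactly equal-cost assignments are resolved deterministically
by the solver.

Splitting at branch points turns one running segment into a parent plus
two daughters, so the number of unbranched segments equals the number of
tracks plus twice the number of bifurcations (plus any mid-track
restarts).

## Tip-relative geometry

For every spot the *raw* (pre-drift-correction) position is compared to
the tip-volume cloud of its crop at the same time step; the nearest point
(exact nearest neighbour via a k-d tree) defines the cell→tip vector and
the tip distance.  Raw positions are used deliberately: the tip clouds
are defined in raw image coordinates, and correcting one but not the
other would shear the geometry.  A spot is *horizontally located* when
this vector's vertical angle is strictly below 45°, i.e.
|dz| < √(dx²+dy²); the boundary case counts as not horizontal, and a
zero vector (distance-0 contact) counts as horizontal with a warning.
Attachment annotations are intervals `(segment, first, last)`; spots on
annotated segments are `attached` inside any interval and `free`
outside, all other spots `unannotated`.  Because axial resolution can
hide attachment when a cell sits directly above or below the tip,
attachment proportions should be assessed on the horizontal subset.  The
nearest tip-end track (ties to the lowest id) is computed and exported
for completeness although it carries little predictive value; drift
correction uses the tip-end positions directly.

## Drift correction

For each interval [t, t+1], each cell's movement has subtracted from it
the weighted average of the tip-end-track movements over the same
interval, with weights ∝ 1/d² to each tip at the interval's *start* step
(start rather than end for causality and determinism).  Weights
normalise to 1; a cell within ε = 1e-9 µm of a tip takes weight 1 on it
(the 1/d² limit); tips undefined at either end of an interval are
dropped and the remaining weights renormalised.  Only horizontal
components are corrected — axial movement is dominated by measurement
noise, and tip growth is predominantly lateral — so the corrected z
series equals the raw one exactly.  Corrected positions anchor each
segment at its raw first position and accumulate corrected movements.
Two exact guarantees follow from the construction and are enforced by
tests: a uniform bulk displacement applied to all cells and tips cancels
exactly, and a cell that rides a single tip corrects to a static track.
Tip context is *not* recomputed on corrected positions.

## Motility statistics

**MSD** is the mean squared straight-line displacement over a lag τ,
computed in 3D per track and then averaged unweighted across tracks
(tracks shorter than τ+1 are excluded, not zeroed).  Linear growth
indicates Brownian motion with slope = diffusion rate; upward curvature
persistent directed movement; downward curvature confinement.  Comparing
raw and corrected MSD quantifies how much persistence is tip-coupled.

**Velocity autocorrelation** at lag τ is the mean dot product of
horizontal step vectors τ apart, normalised by the track's mean squared
single-step horizontal displacement, averaged per track then across
tracks.  Horizontal only: axial resolution produces a "jitter" artefact —
negative single-step autocorrelation in z — that would contaminate the
statistic, whereas MSD is insensitive to such short-term noise and stays
3D.

**Speed heterogeneity.**  Instantaneous horizontal speed (µm per step) is
regressed on sample id, then on sample id plus cell (segment) id, both
categorical; the nested models are compared with an F-test
(`statsmodels` OLS + `anova_lm`) and the percentage RSS reduction is
reported as the share of speed variability attributable to stable
between-cell differences.

**Tip attraction/repulsion.**  Per spot, the drift-corrected movement
over the subsequent step is projected onto the unit vector toward the
nearest tip point (positive = toward the tip).  The projection is used
instead of the change in distance because with a complex tip surface
random motion does not change the distance symmetrically.  Spots whose
raw position lies within 1 µm (strictly) of a lateral crop edge are
excluded — their outward movement can leave the imaged volume.  Moves are
split at 10 µm of initial raw tip distance (the boundary value joins the
far group) and each group's mean projection is tested against zero with
a classic one-sample two-sided t-test; group tables also report the
median projection and the mean horizontal movement magnitude.  Beyond
15 µm an OLS of projection on distance tests whether attraction still
varies with distance.  The projection uses the full 3D vectors (so
|m| ≤ |movement| holds exactly); the reported mean movement magnitude is
horizontal, consistent with the horizontal-only speed statistics.

## The tip-distance model

Radial cell movement is modelled as undirected diffusion D (independent
of distance) plus directed velocity v(d), positive away from the tip.
Under a stable distance distribution the zero-flux steady state of
∂y/∂t = ∂_d(D ∂_d y − v y) is y(d) ∝ exp(∫₀^d k(u)du) with k = v/D; only
the ratio k is identifiable from a distance distribution, and no API
exposes D alone.  (The second-order two-sided form D y″ = v y′ admits
this y as a solution only for constant k; the zero-flux conservation
form is the equation actually consistent with the exponential steady
state, and is what the likelihood implements.)

k(d) is piecewise linear: k1 below d1, k2 above d2, linear between
(0 ≤ d1 ≤ d2).  Its integral is piecewise quadratic and evaluated in
closed form.  The log-likelihood of distances on [0, d_max] is
Σᵢ ∫₀^{dᵢ} k − n·log Z with Z = ∫₀^{d_max} exp(∫₀^u k) du computed by
piecewise Gauss–Legendre quadrature (200 nodes per smooth piece, exponent
shifted by its maximum to avoid overflow; agrees with adaptive quadrature
to well below 1e-8).  d_max defaults to the maximum observed distance;
the normalisation depends on it, so it is configurable.  Fitting defaults
to all spots' nearest-tip distances, with an option to apply the edge
exclusion first.

**Optimisation.**  Parameters are transformed to an unconstrained space
(nested logistic gaps enforce 0 ≤ d1 ≤ d2 ≤ d_max, k1/k2 free) and the
likelihood — only piecewise smooth in the breakpoints — is maximised by
Nelder–Mead from multiple starts, with a tighter simplex polish of the
winner.  Standard errors come from the inverse observed information,
computed by central-difference Hessian in the *original* parameter space
(steps 6e-4·max(0.5, |θ|)); computing it on the transformed scale would
require a delta-method back-transform for no accuracy gain.  The closed
form of the cumulative integral tolerates the slightly negative d1 probed
by differencing at the boundary.  Negative Hessian variances (possible
when a breakpoint is unidentified) yield NaN standard errors with a
warning rather than a crash.

**Simplification.**  When |d1|/SE(d1) < 1.96, d1 is pinned to 0, making k
fall linearly from k1 with slope (k2−k1)/d2 out to d2; otherwise the fit
is returned unchanged.  A zero or undefined SE(d1) keeps the fitted value
with a warning; the rule is idempotent at d1 = 0.

**Identifiability caveat.**  When the true d1 is at or near 0, the
likelihood has a ridge trading d1 against k1 (a slightly positive d1 with
a lower k1 fits almost equally well), so k1's standard error is much
larger than the other parameters'.  The parameter-recovery simulation in
`scripts/acceptance.py` therefore samples by *stratified* inverse CDF
(one jittered draw per equal-probability stratum, seeded): still
unbiased, but with Monte Carlo noise small enough that the check
exercises the estimator and its implementation rather than the luck of
one iid draw.  Plain iid sampling is the default everywhere else and is
separately verified to recover the truth within three standard errors.

## Synthetic data

The generator emulates one cropped field: `n_tips` tips (default 3) of
radius 8 µm drift at 0.5 µm/step in fixed horizontal directions; tip
volumes are emitted as deterministic Fibonacci-sphere clouds (120 points:
surface plus an interior shell) and tip-end tracks as the tip centres.
Cells move per step as

- tip-coupled drift: the inverse-square-weighted average of tip
  movements — exactly the reference model drift correction assumes;
- radial convection-diffusion relative to the nearest tip centre: the
  surface distance takes a reflected 1-D step Δd = D·k(d) + √(2D)·ξ, so
  with a single static tip the surface distance follows exactly the 1-D
  steady state the distance model fits (the √(2D) step size is what makes
  the stationary density exp(∫k) for Fokker–Planck diffusion D);
- angular diffusion over the sphere (tangential Gaussian, σ = 2 µm per
  axis), which leaves the radial coordinate untouched.

Divisions occur with probability 0.002 per cell-step, duplicating the
cell with a 0.75 µm offset; exported z carries independent N(0, 2 µm)
measurement noise, reproducing the negative axial single-step
autocorrelation of real stacks without affecting true motion; cells
reflect at crop bounds (counted in the ledger).  Defaults — 200 cells,
70 steps, D = 4 µm²/step, truth profile k1 = 0.293, d2 = 14.95,
k2 = −0.098 — give per-step movements of ~3 µm and near/far directed
movements of a few tenths of a µm per step, the regime the analysis is
designed for, while the full pipeline runs in well under two minutes on
one CPU.  Emitted branch ids are placeholders unique per concurrent cell
(keeping spot keys unique) but carry no lineage structure; attachment
intervals are expressed against the segment ids that branch resolution
reproducibly assigns.  A ground-truth ledger records true positions,
surface distances, intrinsic displacements, divisions, tip centres and
reflections, and the same scenario and seed reproduce byte-identical
CSVs.

What passing synthetic tests does *not* show: the generator's tips are
spheres with centre-based convection while the analysis measures
distances to cloud points (a deliberate mild mismatch testing
robustness), cells are independent (no crowding, no adhesion dynamics),
division timing is memoryless, and speeds are homogeneous across cells
unless configured otherwise — conclusions about real tissue require the
real tracked data.

## Problem sizes used in tests

Test simulations are sized for signal, not realism: recovery and
calibration checks use 20 000 sampled distances, 150–400 cells over
40–70 steps, 500-track closed-form checks, 1000-replicate type-I
calibration of the attraction t-test (direct move-level simulation), and
a 10-replicate power check of the near-repulsion/far-attraction sign
pattern at the default scenario size.  Statistical assertions use
tolerances derived from the corresponding sampling distributions (binomial
CI for rejection rates, CLT bands for means), and all stochastic tests are
seeded.

## Known limitations

- Per-frame-pair matching cannot trade a worse match now for a better
  one later; pathological lineages could in principle be mis-resolved
  where a global optimisation would succeed.
- The attraction statistic conditions on the raw-position tip distance
  but scores drift-corrected movement; near sharply curved tip surfaces
  the projection direction is only as good as the cloud sampling.
- Standard errors from the observed information are asymptotic; near the
  d1 = 0 boundary the d1/k1 ridge makes SE(d1) and SE(k1) wide and only
  approximately Gaussian.
- The distance model is 1-D: it ignores the geometric (volume) factor a
  3-D shell around a convex tip would add to the density, consistent
  with treating d as distance to a locally extended surface.
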