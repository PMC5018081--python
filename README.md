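# capmotion

Analysis of 3D cell tracks of **cap mesenchyme (CM) cells** — the nephron
progenitors that swarm around each **ureteric tip** in the developing
kidney.  Live-imaged explants yield manually tracked cell positions at 15-
or 20-minute intervals alongside a point-cloud representation of each tip
volume and manually tracked tip extremities.  This package turns such
spot/track tables into motility statistics and a mechanistic model of how
the cap stays attached to its niche:

- **Branch resolution** — tracking exports do not distinguish daughter
  cells after mitosis; positions at consecutive time steps are
  re-associated (≤1 predecessor, ≤2 successors per position, minimising
  first unmatched endpoints/bifurcations and then total matched distance),
  branch points are identified, and lineages are split into unbranched
  analysis segments.
- **Tip-relative geometry** — per spot: the vector and distance to the
  nearest tip-volume point, the nearest tip-end track, a horizontal/
  vertical classification (vertical angle < 45°), and attachment flags
  mapped from annotation intervals.
- **Drift correction** — tissue and tip movement is spatially
  heterogeneous; each cell's per-interval movement has subtracted from it
  the inverse-square-distance-weighted average of the tip-end-track
  movements (horizontal components only), isolating intrinsic motility.
- **Motility statistics** — 3D mean squared displacement (MSD) and
  horizontal velocity autocorrelation per step-length group; between-cell
  speed heterogeneity via nested regression (speed ~ sample vs
  speed ~ sample + cell, F-test and % RSS reduction); and the tip
  attraction/repulsion statistic: the projection of each drift-corrected
  next-step movement onto the direction of the nearest tip point, with
  1 µm edge exclusion, a 10 µm near/far split, one-sample t-tests, and a
  far-field (>15 µm) distance-trend regression.
- **Tip-distance model** — a steady-state convection–diffusion model of
  the distance d of a cell to the tip surface.  With diffusion D and
  directed radial velocity v(d) (positive = repulsion), the zero-flux
  steady state is

      y(d) = y(0) · exp(∫₀^d k(u) du),   k(d) = v(d)/D,

  with k(d) piecewise linear in four parameters (k1 below d1, k2 above
  d2, linear between).  The model is fitted to observed nearest-tip
  distances by maximum likelihood (`TipDistanceModel.fit()` →
  `TipDistanceResults` with estimates, standard errors, `summary()`), and
  a simplification step pins d1 to 0 when it is not significantly
  different from 0.
- **Synthetic data** — a generator producing schema-identical datasets
  with drifting tips, tip-coupled cell drift, distance-dependent radial
  convection, divisions, attachment annotation and axial ("z-jitter")
  measurement noise, plus a ground-truth ledger; every stage is testable
  without any external download.

## Worked example

Run the whole pipeline on a simulated dataset (200 cells, 70 steps, 3
drifting tips, repulsive near-field / attractive far-field truth profile):

```python
from capmotion.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    data_dir="demo/data", out_dir="demo/out",
    stages=("simulate", "resolve", "context", "drift", "motility", "fit"),
    seed=17,
)
report = run_pipeline(cfg)
```

The run report (abridged) prints:

```
"resolve":  {"n_spots": 15070, "n_tracks": 200, "n_segments": 270}
"motility": {"near_mean_m": -0.211, "far_mean_m": 0.573, ...}
"fit":      {"k1": 0.2987, "k2": -0.0939, "converged": true}
```

Reading: 200 lineages containing 35 divisions resolve into 270 unbranched
segments; after drift correction, cells within 10 µm of the tip move on
average 0.21 µm per step **away** from it (repulsion) and cells beyond
10 µm move 0.57 µm per step **toward** it (attraction), both highly
significant (`demo/out/stats/attraction.csv`):

```
group     n    mean_m  median_m  mean_abs_movement         t            p
 d<10  4462 -0.211107 -0.161755           2.853559 -4.679765 2.957134e-06
 d>10 10338  0.572581  0.543402           2.899063 18.404956 1.841935e-74
```

and the maximum-likelihood fit of the distance model to the measured
nearest-tip distances recovers the generative profile
(truth k1 = 0.293, k2 = −0.098): the distribution of cap cells around the
tip is quantitatively explained by near-field repulsion balanced by
far-field attraction.

The same stages are available as a CLI
(`capmotion simulate | summarize | resolve-branches | tip-context |
drift-correct | fit-model | run`).

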