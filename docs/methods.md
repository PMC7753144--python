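# Methods

This note documents the statistical models palmkit implements, the defaults
it ships, the assumptions behind the synthetic-data generator, and the design
choices made where the underlying procedures were genuinely open.

## Blink-statistics counting (qPALM)

### Model

An emitter's appearance count is geometric with bleaching probability *p*
per appearance; *m* independent emitters give the negative binomial
P(n | m, p) = C(n−1, m−1)·p^m·(1−p)^(n−m) (implemented via
`scipy.stats.nbinom`). Detection of each protomer of a dimer is an
independent Bernoulli(*d*) event; conditioning on at least one detection
gives the single-emitter probability q = 2(1−d)/(2−d), the unique
binomial-detection relation consistent with the calibration pair used here
(q = 0.35 ↔ d ≈ 0.79). The labeling efficiency *L* (0.81, from quantitative
western blotting; consumed as a constant, never recomputed) enters only
through d_abs = d·L.

All pmfs and the simulator condition on ≥ 1 detected protomer — clusters
with zero detections are unobservable — which is required for the
detectability correction

  f_true = (f_obs/P₂) / (f_obs/P₂ + (1−f_obs)/P₁),  P₁ = d_abs, P₂ = 1−(1−d_abs)²

to be the exact inverse of the generative thinning.

### Fitting

* `fit_p`: closed-form geometric MLE p̂ = 1/mean(n).
* `fit_q`, `fit_mixture`: 1-D maximum likelihood on the binned counts
  (multinomial likelihood, pmfs renormalised over the truncation window
  n ≤ n_max; bounded scalar minimisation, xatol 1e−10). A least-squares
  objective on the normalised histogram is available
  (`fit_mixture(..., objective="ls")`) since histogram fitting is sometimes
  done that way; MLE is the default.
* Uncertainty: cluster-level bootstrap (multinomial resampling of the
  histogram, B = 1000 by default, minimum 100), percentile 95% interval and
  bootstrap SD, deterministic given the seed.
* Boundary solutions (e.g. an all-singleton histogram driving q̂ → 1) are
  flagged (`at_boundary`), not silently returned as converged.

The mixture is restricted to monomer + dimer, matching the two-state biology
it serves; `pmf_appearances` supports general *m* for extension.

### Statistical resolution of the mixture fit

The observed mixture can be rewritten as
[w·q + (1−w)]·Geom(p) + w·(1−q)·NB(2, p): only the NB(2) weight w(1−q) is
identifiable, which at d_abs = 0.64 amplifies the uncertainty of the dimer
weight by ≈ 2.1×. The Fisher information per observed cluster then bounds
the achievable SD of the corrected dimer fraction at ≈ 0.035 (truth 0.71)
and ≈ 0.020 (truth 0.05) for 5,000 clusters. The estimator attains this
bound (it is the MLE), so quoted ± values at the few-percent level on
similar sample sizes should be read as one standard error, and no
appearance-count-histogram method can do materially better at that n. The
bootstrap CIs reflect the true spread and achieve nominal coverage (tested).

### Appearance extraction and nanocluster grouping

Localizations join an open appearance event when within `merge_radius`
(default 30 nm ≈ 3×σ) of its running centroid and within `max_dark_frames`
(default 3) skipped frames; otherwise they open a new event. Event centroids
are grouped into nanoclusters by DBSCAN (eps 50 nm, min_events 1, isolated
events forming singletons). These four constants are reported in every CLI
manifest; they are acquisition-dependent and should be revisited when frame
rates or densities differ substantially from the defaults below.

## NeNA localization precision

Nearest-neighbour distances between consecutive-frame localizations are
histogrammed (1 nm bins, r ≤ 150 nm) and fitted by least squares with
A·(r/2σ²)·e^(−r²/4σ²) + (1−A)·2r/r_max², i.e. the same-molecule Rayleigh
term (mode at √2σ) plus a linear ramp for uncorrelated neighbours. At least
100 adjacent-frame pairs are required. "Adjacent" means frame offset exactly
+1. The estimate is translation invariant and feeds (i) the default
appearance-merge radius and (ii) the MSD noise floor.

## Single-particle tracking

### Linking

Greedy nearest-neighbour, shortest-link-first, with gap closing up to
`max_gap` = 1 skipped frame and displacement limit `max_disp`·(gap+1)
(default 500 nm/frame). Deterministic: ties break toward the lower
localization index. Adequate at sptPALM densities where concurrent emitters
are sparse; it makes no claim at high densities.

### MSD and classification

The time-averaged MSD uses internal lags k = 1…⌊len/2⌋. Classification:

1. **immobile** if the mean of the first two MSD points ≤ k_imm·4σ²
   (k_imm = 3), σ being the localization precision;
2. otherwise the free model (4Dτ + 4σ², intercept fixed) and the confined
   model (P(1−e^(−4D₀τ/P)) + 4σ²) are least-squares fitted on a window of up
   to 10 lags, and **confined** is called only if all three hold:
   * F-ratio test: the confined model's RSS improvement over the free line
     exceeds F_crit = 4 per its one extra degree of freedom. A fixed RSS
     margin is not used because a 2-parameter model that nests the line
     removes ~1/(L−1) of the RSS on L lags by chance alone, which a fixed
     margin cannot track;
   * the fitted confinement time P/(4D₀) lies inside the fitted window — a
     saturating curve that never saturates within the data is just a line;
   * the curvature ratio (observed MSD at the window end over the
     extrapolation of the first-two-lag slope) is below 0.5.
3. **free** otherwise. The apparent D always comes from the first-4-lag
   slope, also for confined tracks, matching how per-state coefficients are
   conventionally reported.

Tracks must supply at least 8 lags (16 points) for classification: the
relative noise of a time-averaged MSD at lag k is ~√(k/N), and model
selection on shorter curves is noise-dominated (measured confined
sensitivity ~35% on 8–15-point tracks under any rule we tried). Shorter
tracks still yield MSD curves; they are skipped for classification and
counted in the report's `skipped` field. Because diffusion state and track
length are independent in the generative model (and plausibly in cells on
these time scales), fractions over classified tracks are unbiased. Measured
operating point at the default conditions: free specificity ≈ 0.92,
confined sensitivity ≈ 0.86, immobile ≈ 1.00.

Fractions are pooled over tracks (per-cell aggregation can be layered on by
running per-ROI); SEMs come from a bootstrap over tracks (B = 500). Channel
comparison (receptor vs ligand) requires equal frame times and reports
differences with quadrature-combined SEMs.

## Synthetic-data generator

The generator emulates the statistical structure the estimators invert, with
defaults at the emulated study's scales:

| parameter | default | meaning |
|---|---|---|
| p | 0.27 | bleach probability per appearance (cell calibration; 0.34 on glass) |
| d | 0.79 | per-protomer detection efficiency |
| L | 0.81 | labeling efficiency |
| density | 0.63 µm⁻² | Poisson nanocluster density |
| dimer_fraction | 0.05 | resting-state population |
| σ_loc | 10 nm | localization noise |
| fractions | (0.72, 0.14, 0.14) | immobile/confined/free (stimulated condition) |
| D_free, D_conf | 0.10, 0.05 µm²/s | diffusion coefficients |
| r_conf | 100 nm | confinement radius |
| Δt, frames | 0.02 s, 10,000 | acquisition placeholders |
| track length | geometric, mean 30, min 8 | sptPALM track-length scale |

Only the immobile fraction of the stimulated condition is anchored by the
emulated study; the confined/free split is set even, and D values are at the
scales its figures report. Appearances last `on_frames` frames (default 1)
and inter-appearance dark gaps are drawn as (max_dark+1) + Geometric(mean
10), strictly exceeding the extraction threshold, so appearance extraction
at defaults recovers counts exactly on sparse fields — by construction, to
let end-to-end tests isolate estimator error from grouping error.
`on_frames > 1` produces the adjacent-frame re-localizations NeNA needs.
Conditioning on ≥ 1 detection is by rejection with the rejected count
recorded, so detectability corrections can be validated exactly. RNG streams
are split per component (population / timing / noise / flags) from one seed;
identical seed and config give byte-identical outputs.

What the generator does **not** emulate: camera noise and PSF shape (no
image synthesis), drift, photophysical dwell-time structure beyond
appearance counts, inhomogeneous cluster densities, motion blur, and state
switching within a track. Passing tests therefore validate the estimators
under the stated generative assumptions, not the upstream localization
software or detector physics.

## Numerical notes and degenerate inputs

* pmfs are clipped with a 1e−300 floor inside logs; histograms are
  renormalised over their truncation window (n_max = 50 default; mass beyond
  is censored into the top bin by `from_counts`).
* Empty histograms, single-frame NeNA input, < 100 NeNA pairs, empty ligand
  tables and < 30 classifiable tracks raise data errors rather than return
  numbers.
* Zero-area or self-intersecting ROIs are rejected at construction.
* Bootstrap intervals of a one-bin histogram are zero-width by construction.

## Known limitations

* The counting model assumes independent emitters and complete appearance
  separation in time within a cluster; extreme co-blinking would bias counts
  downward.
* The mixture stops at dimers; higher oligomers would inflate the apparent
  dimer fraction.
* Greedy linking is not globally optimal; at high densities use dedicated
  tracking software and import tracks via `TrackSet.from_frame`.
* Per-track diffusion classification below ~16 points is unreliable and is
  deliberately refused rather than silently guessed.
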