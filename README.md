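# palmkit

Quantitative single-molecule localization microscopy for membrane-receptor
biology: **molecular counting from blinking statistics (qPALM)** and
**diffusion-state analysis from single-particle tracking (sptPALM)**, plus a
ground-truth synthetic-data generator for validating every estimator.

The package is aimed at experimentalists who image endogenously tagged
receptors (e.g. MET–mEos4b in HEK293T cells) and start from localization
tables — one detection per row with frame index and 2D position — exported by
any SMLM localization software.

## The models

**Counting.** A photoconvertible fluorophore re-appears ("blinks") until it
photobleaches, which happens with probability *p* after each appearance, so a
single emitter produces a geometric number of appearances,
P(n) = p(1−p)^(n−1). An *m*-emitter cluster produces the negative-binomial
convolution P(n | m, p) = C(n−1, m−1) p^m (1−p)^(n−m). A dimer carries two
tags but may show only one: with per-protomer detection efficiency *d*, an
observed dimer shows a single emitter with probability

  q = 2(1−d)/(2−d),

so the observed-dimer pmf is q·P(n|1,p) + (1−q)·P(n|2,p). Calibrating *p* on
a monomeric reference (CD86) and *q* on a dimeric reference (CTLA4), and
folding the labeling efficiency *L* into an absolute detection efficiency
d_abs = d·L, the per-nanocluster appearance-count histogram of the protein of
interest is fitted as a monomer/dimer mixture. The fitted observed weight is
corrected for detectability (monomers are seen with probability d_abs,
dimers with 1−(1−d_abs)²) to give the true dimer fraction, with bootstrap
confidence intervals.

**Precision and density.** Localization precision σ is estimated by
nearest-neighbour analysis (NeNA): distances between localizations in
adjacent frames follow A·(r/2σ²)·exp(−r²/4σ²) plus a linear background, and
σ is the fitted scale. Nanocluster density (clusters/µm²) is reported per
cell ROI. A colocalization filter restricts counting to receptors near
ligand-channel localizations.

**Tracking.** Localizations are greedily linked into trajectories; each
track's time-averaged MSD is classified as *immobile* (noise floor 4σ²),
*confined* (saturating MSD = P(1−e^(−4D₀τ/P)) + 4σ²) or *free*
(MSD = 4Dτ + 4σ²), and state fractions and apparent diffusion coefficients
are reported with bootstrap SEMs.

## Worked example

```python
from palmkit import fit_mixture
from palmkit.simulate import PhotophysicsConfig, PopulationConfig, SimConfig, sim_blink_counts

cfg = SimConfig(seed=1,
                photophysics=PhotophysicsConfig(p=0.27, d=0.64, L=1.0),
                population=PopulationConfig(density=0.63, dimer_fraction=0.71))
hist, truth = sim_blink_counts(5_000, cfg)
fit = fit_mixture(hist, p=0.27, d_abs=0.64, B=500, seed=1)
print(fit.fractions[1], fit.ci["dimer_true"])
```

prints

```
0.7298... (0.668..., 0.799...)
```

— 5,000 simulated ligand-stimulated nanoclusters whose true dimer fraction is
0.71 are counted back to 0.73 with a 95% bootstrap CI of 0.67–0.80; the
statistical spread of this estimator at this sample size is ≈0.035 (see
`docs/methods.md`). The scripts in `examples/` run the same pattern for each
capability (counting, precision/density, tracking) and print commented
numbers; a thin CLI (`palmkit simulate|count|precision|density|track`) wraps
the same library calls and writes JSON reports with a reproducibility
manifest.

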