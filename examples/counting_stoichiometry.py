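"""Monomer/dimer counting from blinking statistics.

Simulates per-nanocluster blink-count histograms for a resting (5% dimers)
and a ligand-stimulated (71% dimers) receptor population at the calibrated
photophysics (p = 0.27, absolute detection efficiency 0.64), then fits the
monomer/dimer mixture and prints the detectability-corrected dimer fraction
with its bootstrap confidence interval.
"""

from palmkit import fit_mixture
from palmkit.simulate import PhotophysicsConfig, PopulationConfig, SimConfig, sim_blink_counts

P, D_ABS = 0.27, 0.64

for label, f_dimer in (("resting", 0.05), ("ligand-stimulated", 0.71)):
    cfg = SimConfig(
        seed=1,
        photophysics=PhotophysicsConfig(p=P, d=D_ABS, L=1.0),
        population=PopulationConfig(density=0.63, dimer_fraction=f_dimer),
    )
    hist, truth = sim_blink_counts(5_000, cfg)
    fit = fit_mixture(hist, p=P, d_abs=D_ABS, B=500, seed=1)
    lo, hi = fit.ci["dimer_true"]
    print(f"{label:>18}: dimer fraction = {fit.fractions[1]:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f}; truth {f_dimer:.2f}; "
          f"observed weight {fit.fractions_observed[1]:.3f})")

print(
    "\nThe observed weight exceeds the true fraction because dimers, carrying"
    "\ntwo labels, are more likely than monomers to be detected at all; the"
    "\nreported fraction corrects for that detectability bias."
)
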