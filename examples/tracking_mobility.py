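"""Diffusion-state analysis of single-particle tracks.

Simulates a ligand-stimulated three-state receptor population (72% immobile,
14% confined, 14% free), relinks the localizations into trajectories, and
classifies each track from its mean square displacement, reporting state
fractions and apparent diffusion coefficients with bootstrap SEMs.
"""

from palmkit import link_localizations, mobility_report
from palmkit.simulate import DiffusionConfig, SimConfig, sim_tracks

cfg = SimConfig(seed=3, diffusion=DiffusionConfig(fractions=(0.72, 0.14, 0.14),
                                                  n_tracks=1_000))
_, table, truth = sim_tracks(cfg)
print(f"simulated {len(truth.tracks)} tracks -> {len(table)} localizations")

trackset = link_localizations(table, max_disp=500.0, max_gap=1)
rep = mobility_report(trackset, sigma_loc=cfg.sigma_loc, bootstrap_B=500, seed=3)

print(f"classified {rep.n_tracks} tracks "
      f"({rep.settings['skipped']} too short for MSD model selection):")
for state in ("immobile", "confined", "free"):
    print(f"  {state:>9}: fraction {rep.fractions[state]:.2f} "
          f"+/- {rep.fractions_sem[state]:.2f}, "
          f"D = {rep.D_mean[state]:.3f} +/- {rep.D_sem[state]:.3f} um^2/s")

print("\nImmobile tracks sit at the localization-noise floor; the apparent D")
print("of mobile tracks is the early-lag MSD slope / 4. Ligand stimulation")
print("shows up as a growing immobile fraction and shrinking coefficients.")
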