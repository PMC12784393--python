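"""Fit a shared-spline GAM and inspect what it learned.

Each of the 20 amino acids gets one spline over relative sequence position
(0 = N-terminus, 1 = penultimate residue) on a common cubic B-spline basis,
plus a length spline and a C-terminal-lysine coefficient. Here the identity
link predicts absolute CCS on the low-mode cohort of a synthetic dataset,
and the fit is compared against the generator's planted curves.
"""

import dataclasses

import numpy as np

from ccsbimodal import (
    GroundTruthModel,
    SimulationConfig,
    evaluate_spline_recovery,
    fit_shared_spline_gam,
    make_dataset,
    partial_dependence,
    predict,
    spline_property_correlation,
)

truth = dataclasses.replace(GroundTruthModel.default(), noise_sd=5.0)
ds = make_dataset(SimulationConfig(n=20000), seed=2, truth=truth)
idx = [i for i, m in enumerate(ds.true_modes) if m == "low"]
seqs = [ds.records[i].sequence for i in idx]
y = np.array([ds.records[i].ccs for i in idx])

model = fit_shared_spline_gam(seqs, y, "identity")
d = model.diagnostics
print(f"fitted on {d['n_obs']} low-mode records, {d['n_coef']} coefficients, "
      f"edf = {d['edf']:.0f}")
print(f"residual sd = {np.sqrt(d['sigma2']):.2f} Å² (planted noise: 5 Å²)")
print(f"C-terminal K coefficient = {model.beta_cterm_k:+.2f} ± "
      f"{model.se_cterm_k():.2f} Å²")

print("\nglycine spline (centered), with the planted curve:")
grid = np.linspace(0, 1, 5)
pdep = partial_dependence(model, "G", grid, center=True)
planted = truth.splines["G"](grid)
planted = planted - planted.mean()
for t, est, lo, hi, pl in zip(grid, pdep.estimate, pdep.lo95, pdep.hi95, planted):
    print(f"  t={t:.2f}  fit {est:+6.2f}  [{lo:+6.2f}, {hi:+6.2f}]  "
          f"planted {pl:+6.2f}")

recovery, planted_range = evaluate_spline_recovery(model, truth, seqs)
worst = max((r for r in recovery.values() if r.occurrences >= 500),
            key=lambda r: r.rmse)
print(f"\nworst-recovered well-observed residue: {worst.amino_acid} "
      f"(RMSE {worst.rmse:.2f} Å² = "
      f"{worst.rmse / planted_range:.0%} of the planted range)")

corr = spline_property_correlation(model, "residue_mass")
corr_nb = spline_property_correlation(model, "residue_mass",
                                      exclusions=("C", "R", "K", "H"))
print(f"mean contribution vs residue mass: R² = {corr.r_squared:.2f}"
      f"  (non-basic residues only: {corr_nb.r_squared:.2f})")
print("\nThe mass correlation arises because the planted CCS baseline is")
print("linear in peptide mass, so each residue carries a constant")
print("mass-proportional offset on top of its positional curve. In this")
print("cohort every peptide carries exactly one internal R/K/H, so the")
print("shared level of those three splines is absorbed by the intercept and")
print("their means fall off the mass line; the wide bands at the curve ends")
print("reflect shape directions shared across residues that the additive")
print("design only weakly identifies.")
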