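# Methods

## Scope and data model

The package analyzes tables of peptide/charge observations — sequence
(one-letter codes), charge state, measured collisional cross section (CCS,
Å²), a free-text modification annotation and an optional protease label — and
targets the charge-3⁺ cohort whose CCS-versus-mass distribution is bimodal.
All masses are neutral monoisotopic peptide masses (sum of residue masses
plus one water, no protons); this convention reproduces the published
ΔCCS = −27.9 Å² worked example for LAGGGHVGFDNATFLSER to one decimal.
Cysteine is treated as carbamidomethylated (+57.02146 Da) by default, the
form the reference dataset reports; the toggle is exposed.

### Basic sites and the analysis cohort

A basic site is an R, K or H side chain or the N-terminal amine. The amine is
recorded as pseudo-position 0, so it is never "internal"; internal sites are
basic residues at positions 2..n−1, and an internal site at position p of a
length-n peptide lies n − p residues from the C-terminus (adjacent = 1).
"Within five residues" means distance ≤ 5 and "at least seven away" means
distance ≥ 7; distance-6 peptides belong to neither mode-model cohort — the
two definitions deliberately leave that gap, and we keep it.

The cohort filter retains records with the requested charge (default 3),
length ≥ 15, no N-terminal acetylation (MaxQuant token
`Acetyl (Protein N-term)` by default), an allowed protease and, optionally,
an exact basic-site count. Unlabeled records are attributed by terminus rules
with precedence trypsin (C-terminal R/K) > LysN (N-terminal K) > LysC; a
label, when present, always wins. The precedence for multi-compatible
peptides is this package's choice; labeled data are unaffected.

## Mode separation

A two-component full-covariance Gaussian mixture is fitted to the raw
(mass, CCS) points. Full covariances are the least restrictive choice and
the mass–CCS correlation within each band is strong. EM is run from two
deterministic starts and the higher final likelihood wins:

* scikit-learn's k-means initialization (three restarts from the seed), and
* a band start that labels points by the sign of their CCS residual against
  a provisional straight-line mass trend.

The second start matters: when the modes are two long mass-parallel bands,
variance along the mass axis dominates and k-means initialization converges
to a mass split — a markedly worse likelihood optimum that the band start
avoids. A separation diagnostic (CCS-mean gap above one pooled CCS standard
deviation and no near-empty component) flags degenerate single-cloud fits
instead of failing them.

The mixture labels are then distilled into a linear boundary
`ccs = slope·mass + intercept` by minimizing the squared-hinge objective
`C·Σ max(0, 1 − y·f(x))² + ½‖w‖²` with C = 1.0. Mass and CCS are
standardized internally — at strength 1.0 in raw Da/Å² units the ridge term
would be scale-dominated — the intercept is left unregularized (regularizing
it would couple the boundary to the data centroid), and the boundary is
mapped back to raw units. ΔCCS = CCS − boundary; ΔCCS ≤ 0 is the low mode
(ties low, exactly as the rule states). The published coefficients
(0.129799, 278.903) are available as the `reference` strategy; refitting on a
finite sample cannot be expected to reproduce them exactly, so numeric
worked-example checks use the reference strategy.

One estimation property worth knowing: when mode prevalence varies along the
mass axis (longer peptides are more often low-mode), the empirical optimal
boundary tilts slightly relative to the generative center line. Slope and
in-range boundary predictions recover the planted truth within a few
percent, but the intercept — an extrapolation to mass 0, some 1500 Da below
the data — can deviate by ~5%. On symmetric clouds the recovery is well
under 1% for both coefficients.

## Stratified maps and group fractions

Fraction-high maps use unit-width integer bins (the axes — length, proline
count, site distances — are integer-valued; no smoothing). Bins with fewer
than 8 records are masked: their fraction is stored as missing, never zero,
so absence cannot be mistaken for 0%. Marginals and totals include masked
bins. Group fractions over a predicate return exact counts and flag empty
subsets rather than dividing by zero.

Spline summaries average each amino acid's fitted spline over a uniform
101-point grid on [0, 1] (the averaging grid is unspecified in the source
analysis; uniform is the neutral choice) and correlate the per-residue means
with Kyte–Doolittle hydropathy (mode models) or monoisotopic residue mass
(CCS models), excluding carbamidomethylated cysteine by default since its
mass and polarity sit off both scales.

## The shared-spline GAM

For peptide a₁···aₙ the linear predictor is

η = β₀ + Σᵢ₌₁ⁿ⁻¹ f_{aᵢ}((i−1)/(n−2)) + f_len(n) + β_K·1{aₙ=K}.

Every non-C-terminal residue contributes its amino acid's spline at its
relative position — repeat occurrences accumulate by summation — and the
C-terminal residue, guaranteed R or K by the tryptic cohort, contributes only
the lysine indicator (any other terminal residue is rejected at fit time
rather than silently encoded as 0). Logistic link for mode labels, identity
link for absolute CCS.

**Basis.** Cubic B-splines: 12 basis functions on [0, 1] for the shared
position basis, 8 on [15, 55] for the length spline (the cohort's length
range). These defaults resolve central bumps and terminal dips seen in
position effects without overfit; both are configurable. Lengths outside the
basis domain are clamped with a warning (or rejected, per call).

**Penalties.** Each spline block carries a second-difference (P-spline)
curvature penalty plus a ridge penalty; one (derivative, magnitude) pair is
shared by the 20 amino-acid blocks and a separate pair covers the length
spline — per-amino-acid tuning would mean 40 hyperparameters. Defaults are
(1.0, 10⁻³) for both pairs; `tune_penalties` grid-searches them under GCV
(identity) or held-out deviance with a fixed-seed 80/20 split (logistic) and
flags over-smoothed winners by their effective degrees of freedom.

**Fitting.** Identity link: closed-form penalized least squares, residual
variance estimated on n − edf degrees of freedom. Logistic link: iteratively
reweighted least squares to a relative penalized-deviance change below 10⁻⁸
(max 100 iterations; typical fits converge in < 10). With a positive ridge
the objective is strictly convex, so the solution is independent of record
order and of the IRLS start. Confidence bands are pointwise Wald intervals
from the penalized-information ("Bayesian" smoothing-prior) covariance.

**Identifiability.** Adding one constant c to all 20 position splines while
subtracting the matching c·(n−1) from f_len (a linear-in-length function the
length basis represents exactly) changes no prediction; the ridge penalty
selects a unique representative. Total predictions are therefore the stable
quantity; individual curves are reported (and compared with planted truth)
after centering to zero mean over the evaluation grid, with the band
propagated exactly through the centering transform. Two further
weak-identification effects are worth naming. First, any *shape* shared by
all residue splines is nearly exchangeable with a smooth function of length,
so pointwise bands widen toward the position extremes — they are honest but
conservative there. Second, in the exactly-three-basic-site tryptic cohort
every peptide contains exactly one internal basic residue, so the shared
level of the R/K/H splines is confounded with the intercept; their
position-averaged contributions consequently sit off the residue-mass trend
that the other residues follow.

**AUROC** is computed by the Mann–Whitney midrank statistic (ties count ½),
identical to exhaustive positive–negative pair counting.

## Synthetic data generator

The generator exists to make the whole pipeline testable against known
truth; it plants statistical structure, not physics.

* **Sequences.** Tryptic-like (C-terminal R/K drawn 50/50) or LysN-like
  (N-terminal K) peptides with an exact basic-site count: the planted
  internal sites (uniform over R/K/H) are placed at distances drawn from a
  configurable distribution (default uniform on 1..10) and no other basic
  residues occur. Non-site positions are uniform over the 17 non-basic
  residues — flat composition keeps spline recovery well-conditioned.
  Lengths follow a truncated geometric on 15–55 with median ≈ 19, matching
  the analyzed cohort's published length profile; a uniform option exists.
* **Modes.** P(high) is logistic in the distance of the most C-terminal
  internal basic site (coefficient −0.5, the dominant planted effect), the
  proline count (−0.3) and length (−0.05 per residue, saturating at 25
  residues — the positional trend weakens in long peptides), intercept 3.0.
  These defaults reproduce the qualitative real-data pattern: roughly
  60/40 low/high overall, ~2/3 high mode near the C-terminus, ~4/5 low mode
  far from it.
* **CCS.** baseline 0.13·mass + 280, mode offset ±40 Å², plus planted smooth
  per-residue positional effects a·sin(πt) + b·(t−½) with amplitudes of a
  few Å² (drawn once from a fixed seed; part of the model, not the
  simulation noise), a linear length effect (0.5 Å²/residue), a C-terminal-K
  effect (+3 Å²) and homoscedastic Gaussian noise (σ = 10 Å² default; the
  measured reproducibility of real CCS values is better than 1%, so tests
  that probe spline recovery use σ = 5 Å²). Noiseless expectations and true
  modes travel in a separate truth sidecar so the table itself is
  schema-identical to real data.

What the generator does **not** emulate: physically realistic CCS from
structure, heteroscedastic or peptide-specific noise, modification diversity
beyond the Nt-acetylation flag, missed cleavages, proteome-like residue
frequencies (available as an option but not the default), or secondary
conformer peaks. Passing recovery tests therefore demonstrates that the
estimators recover the statistical structure they assume — not that the
biological conclusions transfer to any particular real dataset.

### Recovery evaluation

`evaluate_spline_recovery` compares fitted and planted curves after centering
both, restricted to each residue's observed relative-position support (the
1st–99th percentile of its training positions): basic residues occur only at
planted site positions, so the data carry no information about their curves
elsewhere. RMSE is reported against the combined centered range of all
planted curves. At the study scale (20,000 records, σ = 5 Å², one fit on the
~11,000-record low-mode cohort) every residue with ≥ 500 occurrences
recovers within 6–8% of that range with band coverage at or near 100%.

## Problem sizes and determinism

Default problem sizes — 5,000-point clouds for separator recovery, 20,000
records for GAM recovery, 10,000 for stratification calibration — give
comfortable margins on every recovery criterion while keeping a full test
run around half a minute. All randomness flows through explicit integer
seeds (child seeds are derived deterministically and kept below 2³¹);
pipeline artifacts are plain TSV/JSON with fixed float formatting, so a rerun
with the same config and seed is byte-identical.

Binomial calibration of the fraction maps is asserted with simultaneous
(Bonferroni-corrected) 95% bounds across all unmasked bins; pointwise bounds
asserted at every one of ~50 bins would fail somewhere by construction.

## Known limitations

* The refit separator estimates the empirical decision boundary, which is
  not exactly the generative center line when mode prevalence co-varies with
  mass (see above); the reference strategy sidesteps this for worked
  examples.
* Confidence bands are conservative where the design is weakly identified
  (position extremes, never-observed residues — the latter are flagged).
* The logistic mode model is additive in position, length and composition;
  a planted effect that is multiplicative in (distance × length) is captured
  only approximately, costing ~0.01–0.03 held-out AUROC relative to the
  planted oracle.
* No modeling of multiple conformers per peptide: one CCS per record, as in
  the source tables.
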