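# ccsbimodal

Analysis of the bimodal collisional cross section (CCS) distribution of
charge-3⁺ peptides in trapped ion mobility spectrometry data: separating the
two conformational modes in the mass–CCS plane, stratifying mode membership
by basic-site position, and fitting shared-spline generalized additive models
(GAMs) that predict the CCS mode and absolute CCS from sequence alone.

It is a library for proteomics researchers working with peptide CCS tables
(sequence, charge, CCS), with a thin `ccs-bimodal` command line on top and a
synthetic-data generator that plants known ground truth so every stage of the
pipeline can be validated without external data.

## The science

Charge-3⁺ tryptic peptides populate two mass-correlated CCS bands: a compact
("low") mode and an extended, helix-like ("high") mode. The analysis:

1. **Mode separation.** A two-component Gaussian mixture is fitted to the
   (mass, CCS) cloud and distilled into a linear boundary by an
   L2-regularized squared-hinge fit (regularization 1.0, computed on
   standardized coordinates, reported in raw units). The published reference
   boundary is

   CCS_sep(m) = 0.129799·m + 278.903  (CCS in Å², m in Da),

   and ΔCCS = CCS − CCS_sep(m); ΔCCS ≤ 0 is the low mode, ΔCCS > 0 the high
   mode.

2. **Positional stratification.** Basic sites are R/K/H side chains plus the
   N-terminal amine. For peptides with exactly three basic sites the single
   internal site's distance to the C-terminus strongly orders the high-mode
   fraction; the package builds integer-binned fraction-high maps over
   length, proline count and internal-site distances (bins with < 8 records
   masked).

3. **Shared-spline GAM.** For a peptide a₁a₂···aₙ the linear predictor is

   η = β₀ + Σᵢ₌₁ⁿ⁻¹ f_{aᵢ}((i−1)/(n−2)) + f_len(n) + β_K·1{aₙ = K},

   where every amino acid owns one spline f_a over relative position (0 at
   the N-terminus, 1 at the penultimate residue) on a shared cubic B-spline
   basis, f_len is a length spline, and the C-terminal residue (always R or K
   in tryptic peptides) enters only through the lysine indicator. A logistic
   link maps η to P(high mode); the identity link reads η as CCS in Å².
   Fitting is penalized (P-spline curvature + ridge) least squares / IRLS
   with Wald confidence bands from the penalized-information covariance.

## Worked example

```python
from ccsbimodal import assign_mode, find_basic_sites, monoisotopic_mass, reference_separator

mass = monoisotopic_mass("LAGGGHVGFDNATFLSER")   # 1846.896 Da, neutral
a = assign_mode(mass, 490.7, reference_separator())
print(f"ΔCCS = {a.delta_ccs:+.1f} Å² → {a.mode} mode")
# ΔCCS = -27.9 Å² → low mode

profile = find_basic_sites("GGGNQVSLLNVVMDLKK")
print(profile.n_sites, profile.cterm_distances)
# 3 (1,)  — amine + two lysines; internal site adjacent to the C-terminus
```

The first peptide carries its internal basic site 12 residues from the
C-terminus and sits 27.9 Å² below the boundary (compact mode); the second,
with the internal lysine adjacent to the C-terminal lysine, sits above it
(extended mode). The `examples/` directory has one short script per
capability — worked examples, simulation + mode separation, stratified maps,
GAM fitting and the full pipeline — each printing the numbers it computes.

On synthetic cohorts (10,000 peptides, planted monotone distance effect) the
stratified contrast mirrors the real-data pattern: 67% high mode when the
internal site is within five residues of the C-terminus versus 84% low mode
when it is at least seven away (`examples/03_stratify_by_basic_site.py`).

## Command line

```bash
ccs-bimodal --seed 1 simulate --n 5000 --output data.tsv --truth truth.json
ccs-bimodal --seed 1 separate-modes --input data.tsv --strategy refit --output assigned.tsv
ccs-bimodal stratify --input assigned.tsv --x length --y min_internal_site_distance --output map.tsv
ccs-bimodal fit-gam --input assigned.tsv --subset dist_le5 --target mode --output gam.json
ccs-bimodal run --config pipeline.toml
```

All artifacts are plain TSV/JSON, stamped with the seed and a configuration
hash; identical config + seed reproduces them byte for byte.

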