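"""Shared-spline GAM: design construction, fitting, inference, AUROC."""

import numpy as np
import pytest

from ccsbimodal.basis import BSplineBasis
from ccsbimodal.gam import (
    Penalties,
    auroc,
    build_design_matrix,
    build_design_row,
    default_length_basis,
    default_position_basis,
    fit_shared_spline_gam,
    partial_dependence,
    predict,
    tune_penalties,
)
from ccsbimodal.records import AMINO_ACIDS
from ccsbimodal.synth import GroundTruthModel, SimulationConfig, make_dataset

from conftest import random_sequences


@pytest.fixture(scope="module")
def bases():
    return default_position_basis(), default_length_basis()


def naive_linear_predictor(model, sequence):
    """Residue-by-residue evaluation of the additive model — the independent
    oracle for the design-row construction."""
    pos_b, len_b = model.position_basis, model.length_basis
    n = len(sequence)
    total = model.intercept
    for i, aa in enumerate(sequence[:-1], start=1):
        t = (i - 1) / (n - 2)
        total += float(pos_b.design(t)[0] @ model.coef[model.aa_block(aa)])
    total += float(
        len_b.design(float(n), clamp=True)[0] @ model.coef[model.len_block]
    )
    if sequence[-1] == "K":
        total += model.beta_cterm_k
    return total


class TestBasis:
    def test_partition_of_unity(self):
        b = BSplineBasis(0.0, 1.0, 12)
        x = np.linspace(0, 1, 57)
        assert np.allclose(b.design(x).sum(axis=1), 1.0)

    def test_out_of_domain(self):
        b = BSplineBasis(0.0, 1.0, 12)
        with pytest.raises(ValueError):
            b.design([1.2])
        assert np.allclose(b.design([1.2], clamp=True).sum(), 1.0)

    def test_penalty_annihilates_constants(self):
        b = BSplineBasis(0.0, 1.0, 8)
        P = b.penalty()
        assert np.allclose(P @ np.ones(8), 0.0)


class TestDesignRow:
    def test_tiny_peptide_aak(self, bases):
        pos_b, len_b = bases
        row = build_design_row("AAK", pos_b, len_b)
        p = pos_b.n_basis
        a_block = row[1 : 1 + p]
        expected = pos_b.design(0.0)[0] + pos_b.design(1.0)[0]
        assert np.allclose(a_block, expected)
        # all other amino-acid blocks empty
        rest = row[1 + p : 1 + 20 * p]
        assert np.allclose(rest, 0.0)
        assert row[-1] == 1.0  # C-terminal lysine indicator

    def test_tiny_peptide_aar(self, bases):
        pos_b, len_b = bases
        row_k = build_design_row("AAK", pos_b, len_b)
        row_r = build_design_row("AAR", pos_b, len_b)
        assert np.allclose(row_k[:-1], row_r[:-1])
        assert row_r[-1] == 0.0

    def test_oracle_equivalence_on_random_sequences(self, rng, bases):
        """Design-row predictions equal the naive per-residue sum."""
        pos_b, len_b = bases
        seqs = random_sequences(rng, 100)
        X = build_design_matrix(seqs, pos_b, len_b)
        coef = rng.normal(size=X.shape[1])
        model = _model_with_coef(coef, pos_b, len_b)
        for seq, row in zip(seqs, X):
            assert float(row @ coef) == pytest.approx(
                naive_linear_predictor(model, seq), abs=1e-10
            )

    def test_short_sequence_rejected(self, bases):
        with pytest.raises(ValueError):
            build_design_row("AK", *bases)


def _model_with_coef(coef, pos_b=None, len_b=None):
    from ccsbimodal.gam import SharedSplineGam

    pos_b = pos_b or default_position_basis()
    len_b = len_b or default_length_basis()
    q = len(coef)
    return SharedSplineGam(
        position_basis=pos_b,
        length_basis=len_b,
        link="identity",
        coef=np.asarray(coef, dtype=float),
        cov=np.eye(q) * 1e-4,
        penalties=Penalties(),
    )


class TestPredict:
    def test_zero_coefficient_logistic_is_half(self):
        model = _model_with_coef(np.zeros(2 + 20 * 12 + 8))
        model.link = "logistic"
        assert predict(model, "AAKAAAKAAAAAAAR") == pytest.approx(0.5)

    def test_intercept_only_identity(self):
        coef = np.zeros(2 + 20 * 12 + 8)
        coef[0] = 450.0
        model = _model_with_coef(coef)
        for seq in ("AAKAAAKAAAAAAAR", "GGGNQVSLLNVVMDLKK"):
            assert predict(model, seq) == pytest.approx(450.0)


@pytest.fixture(scope="module")
def planted_identity_fit():
    """Identity-link fit on records from the planted additive CCS model."""
    truth = GroundTruthModel.default()
    truth.noise_sd = 5.0
    ds = make_dataset(SimulationConfig(n=8000), seed=3, truth=truth)
    idx = [i for i, m in enumerate(ds.true_modes) if m == "low"]
    seqs = [ds.records[i].sequence for i in idx]
    y = np.array([ds.records[i].ccs for i in idx])
    fit = fit_shared_spline_gam(seqs, y, "identity")
    return fit, truth, seqs, y


class TestFit:
    def test_residual_variance_estimate(self, planted_identity_fit):
        fit, truth, _, _ = planted_identity_fit
        # σ̂² should approach the planted measurement variance (25 Å⁴)
        assert fit.diagnostics["sigma2"] == pytest.approx(25.0, rel=0.2)

    def test_permutation_invariance(self, rng):
        ds = make_dataset(SimulationConfig(n=800), seed=9)
        seqs = [r.sequence for r in ds.records]
        y = np.array([r.ccs for r in ds.records])
        perm = rng.permutation(len(seqs))
        f1 = fit_shared_spline_gam(seqs, y, "identity")
        f2 = fit_shared_spline_gam([seqs[i] for i in perm], y[perm], "identity")
        assert np.allclose(f1.coef, f2.coef, atol=1e-8)

    def test_logistic_start_invariance(self):
        """With a positive magnitude penalty the objective is strictly convex:
        IRLS from different starts reaches the same solution."""
        ds = make_dataset(SimulationConfig(n=2000), seed=5)
        seqs = [r.sequence for r in ds.records]
        y = (np.array(ds.true_modes) == "high").astype(float)
        f1 = fit_shared_spline_gam(seqs, y, "logistic")
        q = len(f1.coef)
        rng = np.random.default_rng(0)
        f2 = fit_shared_spline_gam(
            seqs, y, "logistic", init_coef=rng.normal(scale=0.05, size=q)
        )
        assert np.allclose(f1.coef, f2.coef, atol=1e-4)

    def test_null_plant_contributions_near_zero(self):
        """With all planted residue effects zero, fitted contributions sit
        inside their own confidence bands around zero almost everywhere."""
        truth = GroundTruthModel.default()
        truth.splines = {aa: type(next(iter(truth.splines.values())))(0.0, 0.0)
                         for aa in truth.splines}
        truth.noise_sd = 5.0
        ds = make_dataset(SimulationConfig(n=6000), seed=6, truth=truth)
        idx = [i for i, m in enumerate(ds.true_modes) if m == "low"]
        seqs = [ds.records[i].sequence for i in idx]
        y = np.array([ds.records[i].ccs for i in idx])
        fit = fit_shared_spline_gam(seqs, y, "identity")
        grid = np.linspace(0, 1, 41)
        inside = []
        for aa in AMINO_ACIDS:
            pdep = partial_dependence(fit, aa, grid, center=True)
            inside.extend((pdep.lo95 <= 0) & (0 <= pdep.hi95))
        assert np.mean(inside) >= 0.95

    def test_non_rk_terminus_rejected(self):
        with pytest.raises(ValueError, match="C-terminal R/K"):
            fit_shared_spline_gam(
                ["AAAAAAAAAAAAAAA"] * 10, np.zeros(10), "identity"
            )

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            fit_shared_spline_gam(["AAK"] * 5, np.zeros(4), "identity")


class TestPartialDependence:
    def test_band_shrinks_with_more_data(self):
        truth = GroundTruthModel.default()
        ds = make_dataset(SimulationConfig(n=4000), seed=8, truth=truth)
        seqs = [r.sequence for r in ds.records]
        y = np.array([r.ccs for r in ds.records])
        fit_small = fit_shared_spline_gam(seqs[:1000], y[:1000], "identity")
        fit_big = fit_shared_spline_gam(seqs, y, "identity")
        grid = np.linspace(0, 1, 21)
        for aa in "ALG":
            w_small = np.mean(
                partial_dependence(fit_small, aa, grid).hi95
                - partial_dependence(fit_small, aa, grid).lo95
            )
            w_big = np.mean(
                partial_dependence(fit_big, aa, grid).hi95
                - partial_dependence(fit_big, aa, grid).lo95
            )
            assert w_big < w_small

    def test_unknown_amino_acid(self, planted_identity_fit):
        fit = planted_identity_fit[0]
        with pytest.raises(KeyError):
            partial_dependence(fit, "B")

    def test_unobserved_amino_acid_flagged(self):
        """A residue absent from training has a penalty-governed band and is
        flagged as carrying no information."""
        seqs = ["AAGGLLSSVVTTNNK"] * 300  # no tryptophan anywhere
        rng = np.random.default_rng(0)
        y = 500 + rng.normal(0, 5, size=300)
        fit = fit_shared_spline_gam(list(seqs), y, "identity")
        pdep = partial_dependence(fit, "W")
        assert pdep.flagged


class TestAuroc:
    def test_worked_example(self):
        # brute force over the 4 positive-negative pairs gives 3/4
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_with_ties(self, rng):
        """Midrank AUROC equals exhaustive pairwise counting (ties → ½)."""
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert auroc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestTunePenalties:
    def test_single_point_grid(self):
        ds = make_dataset(SimulationConfig(n=600), seed=2)
        seqs = [r.sequence for r in ds.records]
        y = np.array([r.ccs for r in ds.records])
        pen = Penalties()
        res = tune_penalties(seqs, y, "identity", [pen])
        assert res.best is pen

    def test_oversmoothed_grid_flagged(self):
        ds = make_dataset(SimulationConfig(n=600), seed=2)
        seqs = [r.sequence for r in ds.records]
        y = np.array([r.ccs for r in ds.records])
        huge = Penalties(pos_deriv=1e9, pos_ridge=1e6, len_deriv=1e9,
                         len_ridge=1e6)
        res = tune_penalties(seqs, y, "identity", [huge])
        assert res.flagged

    def test_grid_selects_near_optimal_recovery(self):
        """GCV's pick recovers the planted curves nearly as well as the best
        grid member judged directly against the ground truth."""
        from ccsbimodal.synth import evaluate_spline_recovery

        truth = GroundTruthModel.default()
        truth.noise_sd = 5.0
        ds = make_dataset(SimulationConfig(n=4000), seed=4, truth=truth)
        idx = [i for i, m in enumerate(ds.true_modes) if m == "low"]
        seqs = [ds.records[i].sequence for i in idx]
        y = np.array([ds.records[i].ccs for i in idx])
        grid = [
            Penalties(pos_deriv=d, pos_ridge=1e-3, len_deriv=d, len_ridge=1e-3)
            for d in (0.1, 10.0, 1e4)
        ]
        res = tune_penalties(seqs, y, "identity", grid)
        rmses = []
        for entry in res.table:
            fit = fit_shared_spline_gam(seqs, y, "identity", entry["penalties"])
            rec, _ = evaluate_spline_recovery(fit, truth, seqs)
            rmses.append(np.mean([r.rmse for r in rec.values()]))
        chosen_idx = [e["penalties"] for e in res.table].index(res.best)
        assert rmses[chosen_idx] <= 1.5 * min(rmses)
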