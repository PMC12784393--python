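"""Two-stage CCS mode separation in the mass–CCS plane.

Charge 3+ peptides form two mass-correlated CCS bands. The separation
procedure fits a two-component Gaussian mixture to the (mass, CCS) cloud,
then distills the mixture classification into a linear boundary

    CCS_separator = slope · mass + intercept

by minimizing an L2-regularized squared hinge loss. A peptide's ΔCCS is its
CCS minus the boundary prediction at its mass; ΔCCS ≤ 0 is the low mode and
ΔCCS > 0 the high mode. The published reference boundary
(0.129799 · mass + 278.903) is available as a fixed strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.mixture import GaussianMixture

from .features import monoisotopic_mass
from .records import PeptideRecord

#: Published linear boundary between the low and high CCS modes, fitted on
#: the full charge-3+ reference dataset (slope in Å²/Da, intercept in Å²).
REFERENCE_SLOPE = 0.129799
REFERENCE_INTERCEPT = 278.903


class ConvergenceError(RuntimeError):
    """An iterative fit did not converge; carries the last state."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class SeparatorModel:
    """Linear mass→CCS boundary defining ΔCCS and mode membership."""

    slope: float
    intercept: float

    def predict(self, mass) -> np.ndarray | float:
        return self.slope * np.asarray(mass) + self.intercept


@dataclass
class GmmFit:
    """Two-component full-covariance Gaussian mixture on (mass, CCS).

    Component 0 is always the lower-CCS-mean component (the low mode);
    ``labels`` are hard assignments by maximum responsibility and
    ``separation_ok`` flags whether the two components are meaningfully
    distinct (mean separation and balanced weights).
    """

    means: np.ndarray  # (2, 2)
    covariances: np.ndarray  # (2, 2, 2)
    weights: np.ndarray  # (2,)
    responsibilities: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) in {0, 1}; 1 = high-CCS component
    log_likelihood: float
    separation_ok: bool


@dataclass(frozen=True)
class ModeAssignment:
    delta_ccs: float
    mode: Literal["low", "high"]


def fit_gmm2(points: Sequence[tuple[float, float]] | np.ndarray, seed: int) -> GmmFit:
    """EM fit of a 2-component Gaussian mixture to the (mass, CCS) cloud.

    Full covariances, k-means-style initialization with the given seed, hard
    labels by maximum responsibility. Components are reordered so component 0
    has the lower CCS mean. Degenerate single-cloud inputs converge but are
    flagged via ``separation_ok``.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (mass, ccs)")
    if len(X) < 4:
        raise ValueError(f"need at least 4 points to fit two components, got {len(X)}")
    common = dict(
        n_components=2, covariance_type="full", max_iter=500, tol=1e-6,
        random_state=seed,
    )
    # Two deterministic starts, best final likelihood wins. The k-means start
    # tends to split along the dominant (mass) axis; the second start labels
    # points by their CCS residual against a provisional mass trend, which is
    # the right initialization when the modes are two mass-parallel bands.
    gm = GaussianMixture(n_init=3, **common).fit(X)
    resid = X[:, 1] - np.poly1d(np.polyfit(X[:, 0], X[:, 1], 1))(X[:, 0])
    labels0 = (resid > 0).astype(int)
    if 0 < labels0.sum() < len(X):
        means0 = np.array([X[labels0 == k].mean(axis=0) for k in (0, 1)])
        w0 = np.array([(labels0 == 0).mean(), (labels0 == 1).mean()])
        precs = []
        for k in (0, 1):
            cov_k = np.cov(X[labels0 == k].T) + 1e-6 * np.eye(2)
            precs.append(np.linalg.inv(cov_k))
        gm_band = GaussianMixture(
            weights_init=w0, means_init=means0,
            precisions_init=np.array(precs), **common,
        ).fit(X)
        if gm_band.lower_bound_ > gm.lower_bound_:
            gm = gm_band
    if not gm.converged_:
        raise ConvergenceError("Gaussian mixture EM did not converge", state=gm)
    order = np.argsort(gm.means_[:, 1])  # by CCS mean: low first
    resp = gm.predict_proba(X)[:, order]
    means = gm.means_[order]
    covs = gm.covariances_[order]
    weights = gm.weights_[order]
    labels = np.argmax(resp, axis=1)
    # separation diagnostic: CCS means at least one pooled CCS sd apart and
    # neither component nearly empty
    sds = np.sqrt(covs[:, 1, 1])
    gap = (means[1, 1] - means[0, 1]) / np.sqrt(np.mean(sds**2))
    separation_ok = bool(gap > 1.0 and weights.min() > 0.02)
    return GmmFit(
        means=means,
        covariances=covs,
        weights=weights,
        responsibilities=resp,
        labels=labels,
        log_likelihood=float(gm.score(X) * len(X)),
        separation_ok=separation_ok,
    )


def _squared_hinge_objective(params, Xs, y, C):
    w = params[:2]
    b = params[2]
    margins = 1.0 - y * (Xs @ w + b)
    hinge = np.maximum(margins, 0.0)
    loss = C * np.sum(hinge**2) + 0.5 * np.dot(w, w)
    grad_f = -2.0 * C * y * hinge
    grad_w = Xs.T @ grad_f + w
    grad_b = np.sum(grad_f)
    return loss, np.concatenate([grad_w, [grad_b]])


def fit_linear_separator(
    points: Sequence[tuple[float, float]] | np.ndarray,
    labels: np.ndarray,
    regularization: float = 1.0,
) -> SeparatorModel:
    """Squared-hinge linear boundary between the two mixture classes.

    The loss ``C·Σ max(0, 1 − y·f(x))² + ½‖w‖²`` is minimized on internally
    standardized (mass, CCS) coordinates — regularization at strength 1.0 in
    raw Da/Å² units would be scale-dominated — with an unregularized
    intercept, and the boundary is mapped back to raw units as
    ``ccs = slope·mass + intercept``.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both mode labels must be present to fit a separator")
    y = np.where(labels == classes.max(), 1.0, -1.0)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    res = minimize(
        _squared_hinge_objective,
        x0=np.array([0.0, 1.0, 0.0]),
        args=(Xs, y, float(regularization)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    w1, w2, b = res.x
    if abs(w2) < 1e-12:
        raise ConvergenceError("degenerate separator: boundary vertical in CCS", res)
    # w1*(mass-mu0)/sd0 + w2*(ccs-mu1)/sd1 + b = 0  ->  ccs = slope*mass + intercept
    slope = -(w1 / sd[0]) * (sd[1] / w2)
    intercept = mu[1] - (b * sd[1]) / w2 + (w1 / sd[0]) * (sd[1] / w2) * mu[0]
    return SeparatorModel(slope=float(slope), intercept=float(intercept))


def reference_separator() -> SeparatorModel:
    """The published low/high mode boundary."""
    return SeparatorModel(slope=REFERENCE_SLOPE, intercept=REFERENCE_INTERCEPT)


def assign_mode(mass: float, ccs: float, separator: SeparatorModel) -> ModeAssignment:
    """ΔCCS and mode for one (mass, CCS) point; ΔCCS = 0 ties go low."""
    if mass <= 0 or ccs <= 0:
        raise ValueError("mass and ccs must be positive")
    delta = ccs - separator.predict(mass)
    return ModeAssignment(delta_ccs=float(delta), mode="low" if delta <= 0 else "high")


@dataclass
class SeparationResult:
    assignments: list[ModeAssignment]
    separator: SeparatorModel
    n_low: int
    n_high: int
    gmm: GmmFit | None = None


def separate_dataset(
    records: Sequence[PeptideRecord],
    strategy: Literal["refit", "reference"] = "reference",
    seed: int = 0,
    regularization: float = 1.0,
) -> SeparationResult:
    """Assign every record a ΔCCS and mode.

    ``refit`` runs the full two-stage procedure (GMM then squared-hinge
    boundary) on these records; ``reference`` applies the published boundary.
    """
    masses = np.array([monoisotopic_mass(r.sequence) for r in records])
    ccs = np.array([r.ccs for r in records])
    gmm = None
    if strategy == "reference":
        sep = reference_separator()
    elif strategy == "refit":
        pts = np.column_stack([masses, ccs])
        gmm = fit_gmm2(pts, seed=seed)
        sep = fit_linear_separator(pts, gmm.labels, regularization=regularization)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    assignments = [
        assign_mode(m, c, sep) for m, c in zip(masses, ccs)
    ] if len(records) else []
    n_low = sum(a.mode == "low" for a in assignments)
    return SeparationResult(
        assignments=assignments,
        separator=sep,
        n_low=n_low,
        n_high=len(assignments) - n_low,
        gmm=gmm,
    )
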