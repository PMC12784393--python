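"""Clamped B-spline bases with P-spline difference penalties."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis on [lo, hi].

    ``n_basis`` cubic (by default) basis functions with equally spaced
    interior knots. The basis is a partition of unity on the interior, so a
    constant function is exactly representable and second-order coefficient
    differences penalize curvature in the P-spline sense.
    """

    lo: float
    hi: float
    n_basis: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError("basis domain must have hi > lo")
        if self.n_basis < self.degree + 1:
            raise ValueError(
                f"need at least degree+1={self.degree + 1} basis functions"
            )

    @property
    def knots(self) -> np.ndarray:
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(self.lo, self.hi, n_interior + 2)[1:-1]
        return np.concatenate(
            [
                np.full(self.degree + 1, self.lo),
                interior,
                np.full(self.degree + 1, self.hi),
            ]
        )

    def design(self, x, clamp: bool = False) -> np.ndarray:
        """Dense (len(x), n_basis) design matrix; rows sum to 1 in-domain."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if clamp:
            x = np.clip(x, self.lo, self.hi)
        elif np.any((x < self.lo) | (x > self.hi)):
            bad = x[(x < self.lo) | (x > self.hi)][0]
            raise ValueError(f"value {bad} outside basis domain [{self.lo}, {self.hi}]")
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        """P-spline difference penalty matrix DᵀD of the given order."""
        D = np.diff(np.eye(self.n_basis), n=order, axis=0)
        return D.T @ D
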