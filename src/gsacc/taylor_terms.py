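"""Second-order Taylor machinery for the expected inverse of X'X + Lambda.

The shrunken normal-equation matrix splits into its expectation
D = N F + Lambda (diagonal under linkage equilibrium) and the random
deviation E = X'X - N F.  The second-order correction to E[(X'X+Lambda)^-1]
is E[D^-1 E D^-1 E] D^-1, and since F and D are diagonal only the diagonal
of P = D^-1 E D^-1 E enters the precision trace.  Its expectation has the
closed form

    E[P_kk] = (N sigma_k^2 / delta_k) ((1 - 2 sigma_k^2)/delta_k
                                        + sum_t sigma_t^2/delta_t),

with delta_k = N sigma_k^2 + lambda_k.  No dense M x M inverse is formed
here; traces are explicit sums over the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .closed_form import PrecisionEstimate

__all__ = ["ShrinkageDiagonal", "expected_P_diagonal", "precision_second_order_general"]


@dataclass(frozen=True)
class ShrinkageDiagonal:
    """Diagonals of the shrinkage matrix Lambda and of D = N F + Lambda."""

    lambda_k: np.ndarray
    delta_k: np.ndarray

    @classmethod
    def from_panel(cls, sigma_k2, N: int, lambda_k) -> "ShrinkageDiagonal":
        sigma_k2 = np.asarray(sigma_k2, dtype=float)
        lambda_k = np.asarray(lambda_k, dtype=float)
        if sigma_k2.shape != lambda_k.shape:
            raise ValueError("sigma_k2 and lambda_k must have the same length")
        if np.any(lambda_k <= 0.0):
            raise ValueError("all lambda_k must be strictly positive")
        return cls(lambda_k=lambda_k, delta_k=N * sigma_k2 + lambda_k)


def _validate(sigma_k2: np.ndarray, lambda_k: np.ndarray) -> None:
    if sigma_k2.shape != lambda_k.shape:
        raise ValueError(
            f"length mismatch: {sigma_k2.size} variances vs {lambda_k.size} shrinkage terms"
        )
    if np.any(sigma_k2 <= 0.0) or np.any(sigma_k2 > 0.5):
        raise ValueError("per-locus variances must lie in (0, 0.5]")
    if np.any(lambda_k <= 0.0):
        raise ValueError("all lambda_k must be strictly positive")


def expected_P_diagonal(sigma_k2, N: int, lambda_k) -> np.ndarray:
    """Expected diagonal of P = D^-1 E D^-1 E for an independent-locus panel."""
    sigma_k2 = np.asarray(sigma_k2, dtype=float)
    lambda_k = np.asarray(lambda_k, dtype=float)
    _validate(sigma_k2, lambda_k)
    delta = N * sigma_k2 + lambda_k
    trace_term = float(np.sum(sigma_k2 / delta))
    return (N * sigma_k2 / delta) * ((1.0 - 2.0 * sigma_k2) / delta + trace_term)


def precision_second_order_general(sigma_k2, N: int, lambda_k, h2: float) -> PrecisionEstimate:
    """Generic second-order precision 1 - lam (tr[F D^-1] + tr[F E[P] D^-1]).

    Works for any positive shrinkage diagonal, not only the equal-contribution
    model; with lambda_k = M lam sigma_k^2 it reduces algebraically to the
    scalar second-order formula.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    sigma_k2 = np.asarray(sigma_k2, dtype=float)
    lambda_k = np.asarray(lambda_k, dtype=float)
    _validate(sigma_k2, lambda_k)
    lam = (1.0 - h2) / h2
    if lam == 0.0:
        return PrecisionEstimate(1.0, "eq4")
    delta = N * sigma_k2 + lambda_k
    first = np.sum(sigma_k2 / delta)
    p_diag = expected_P_diagonal(sigma_k2, N, lambda_k)
    second = np.sum(sigma_k2 * p_diag / delta)
    return PrecisionEstimate(float(1.0 - lam * (first + second)), "eq4")
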