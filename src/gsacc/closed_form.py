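"""Scalar closed-form predictors of GEBV precision (squared accuracy).

All formulas consume a :class:`DesignSpec` with phenotypic variance
normalised to 1 (sigma_g^2 = h2, sigma_e^2 = 1 - h2) and return a
:class:`PrecisionEstimate`.  The variance ratio lambda = (1 - h2)/h2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .freq_models import FreqDistribution, expected_inv_variance, expected_variance_uniform

__all__ = [
    "DesignSpec",
    "PrecisionEstimate",
    "daetwyler_basic",
    "daetwyler_corrected",
    "first_order",
    "second_order_from_variances",
    "second_order_uniform",
    "second_order_ushape",
    "goddard_comparator",
    "single_variance_first_order",
    "adjust_for_marker_coverage",
]


@dataclass(frozen=True)
class DesignSpec:
    """Scalar design of a single-trait genomic evaluation.

    N : reference population size; M : number of SNPs; h2 : heritability.
    """

    N: int
    M: int
    h2: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError(f"h2 must lie in (0, 1], got {self.h2}")

    @property
    def lam(self) -> float:
        """Residual-to-genetic variance ratio (1 - h2)/h2; 0 iff h2 = 1."""
        return (1.0 - self.h2) / self.h2


@dataclass(frozen=True)
class PrecisionEstimate:
    """A precision (reliability) value tagged with the method that produced it.

    ``mc_se`` and ``replicates`` are present only for stochastic methods;
    ``corr2`` carries the secondary squared-correlation estimate of the
    empirical simulator.
    """

    value: float
    method: str
    mc_se: Optional[float] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None
    corr2: Optional[float] = None

    def __float__(self) -> float:
        return float(self.value)


def daetwyler_basic(design: DesignSpec) -> PrecisionEstimate:
    """N h2 / (N h2 + M): the one-locus-at-a-time regression predictor."""
    N, M, h2 = design.N, design.M, design.h2
    return PrecisionEstimate(N * h2 / (N * h2 + M), "eq2")


def daetwyler_corrected(design: DesignSpec) -> PrecisionEstimate:
    """Root of the quadratic obtained when the residual variance is reduced
    to 1 - r^2 h2; the "-" root is the one lying in [0, 1]."""
    N, M, h2 = design.N, design.M, design.h2
    a = M + N * h2
    disc = a * a - 4.0 * N * M * h2 * h2
    # disc >= 0 always: (M + N h2)^2 >= 4 N M h2^2 by AM-GM with h2 <= 1
    return PrecisionEstimate((a - math.sqrt(disc)) / (2.0 * M * h2), "eq3")


def first_order(design: DesignSpec) -> PrecisionEstimate:
    """First-order Taylor predictor N / (N + M lambda)."""
    N, M = design.N, design.M
    return PrecisionEstimate(N / (N + M * design.lam), "eq5")


def _second_order(design: DesignSpec, mean_inv_variance: float, method: str) -> PrecisionEstimate:
    N, M, lam = design.N, design.M, design.lam
    if lam == 0.0:
        return PrecisionEstimate(1.0, method)
    lead = N / (N + M * lam)
    corr = lam * N * M / (N + M * lam) ** 3 * (M - 2.0 + mean_inv_variance)
    return PrecisionEstimate(lead - corr, method)


def second_order_from_variances(design: DesignSpec, sigma_k2: Sequence[float]) -> PrecisionEstimate:
    """Second-order predictor using realised per-locus genotype variances."""
    s = np.asarray(sigma_k2, dtype=float)
    if s.size != design.M:
        raise ValueError(f"expected {design.M} variances, got {s.size}")
    if np.any(s <= 0.0) or np.any(s > 0.5):
        raise ValueError("per-locus variances 2f(1-f) must lie in (0, 0.5]")
    return _second_order(design, float(np.mean(1.0 / s)), "eq6")


def second_order_uniform(design: DesignSpec, f_min: float) -> PrecisionEstimate:
    """Second-order predictor with E[1/sigma^2] under the uniform frequency law."""
    dist = FreqDistribution("uniform", f_min)
    return _second_order(design, expected_inv_variance(dist), "eq7")


def second_order_ushape(design: DesignSpec) -> PrecisionEstimate:
    """Second-order predictor for a U-shaped frequency law, with the
    E[1/sigma^2] correction factor approximated by 2 (its value for
    minimum MAF above ~5%)."""
    N, M, lam = design.N, design.M, design.lam
    if lam == 0.0:
        return PrecisionEstimate(1.0, "eq8")
    lead = N / (N + M * lam)
    return PrecisionEstimate(lead - lam * (M / N) ** 2 * lead**3, "eq8")


def goddard_comparator(design: DesignSpec, f_min: float) -> PrecisionEstimate:
    """Goddard's (2009) closed form, parameterised with log(2 Ne) replaced
    by -log(f_min) and the effective locus count set to M (unlinked SNPs)."""
    if not (0.0 < f_min < 0.5):
        raise ValueError("f_min must lie strictly in (0, 0.5)")
    N, M = design.N, design.M
    if design.lam == 0.0:
        return PrecisionEstimate(1.0, "goddard")
    lam_g = design.lam * M / (-math.log(f_min))
    a = 1.0 + 2.0 * lam_g / N
    sqrt_a = math.sqrt(a)
    ratio = (1.0 + a + 2.0 * sqrt_a) / (1.0 + a - 2.0 * sqrt_a)
    value = 1.0 - lam_g / (2.0 * N * sqrt_a) * math.log(ratio)
    return PrecisionEstimate(value, "goddard")


def single_variance_first_order(design: DesignSpec, f_min: float) -> PrecisionEstimate:
    """First-order predictor under a single shared prior variance of SNP
    effects (GBLUP-style), using the published shrinkage constant."""
    if not (0.0 < f_min < 0.5):
        raise ValueError("f_min must lie strictly in (0, 0.5)")
    N, M, lam = design.N, design.M, design.lam
    if lam == 0.0:
        return PrecisionEstimate(1.0, "eq9")
    # lam_beta = M/(1-2f) * (1-6f^2+2f^3)/3 * lam; the cubic-over-(1-2f)
    # factor is expected_variance_uniform.
    lam_beta = M * expected_variance_uniform(f_min) * lam
    s = math.sqrt(1.0 + 2.0 * lam_beta / N)
    num = 2.0 * f_min - 1.0 + s
    den = 1.0 - 2.0 * f_min + s
    if num <= 0.0 or den <= 0.0:
        raise ValueError(
            f"log argument non-positive (numerator {num:.3g}, denominator {den:.3g}); "
            "N is too small relative to the shrinkage ratio"
        )
    value = 1.0 - (lam * M / N) * (
        1.0 + (1.0 / (1.0 - 2.0 * f_min)) * (lam_beta / (N * s)) * math.log(num / den)
    )
    return PrecisionEstimate(value, "eq9")


def adjust_for_marker_coverage(
    design: DesignSpec,
    b: float,
    method: Callable[..., PrecisionEstimate],
    **kwargs,
) -> PrecisionEstimate:
    """Adjust any closed-form predictor for the proportion ``b`` of genetic
    variance captured by the markers: heritability shrinks to b*h2 and the
    resulting precision is regressed by b."""
    if not (0.0 <= b <= 1.0):
        raise ValueError("b must lie in [0, 1]")
    if b == 0.0:
        return PrecisionEstimate(0.0, "coverage_adjusted")
    base = method(replace(design, h2=b * design.h2), **kwargs)
    return PrecisionEstimate(b * base.value, f"{base.method}+coverage")
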