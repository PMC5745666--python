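"""Allele-frequency distributions on the symmetric support [f_min, 1 - f_min].

Two laws are supported:

* ``uniform`` — constant density 1/(1 - 2 f_min);
* ``ushape``  — density C / (2 f (1 - f)) with C = 1 / log((1 - f_min)/f_min),
  the drift-equilibrium spectrum truncated to the support.

Both expose the moments of the per-locus genotype variance
``sigma^2 = 2 f (1 - f)`` needed by the closed-form precision predictors, an
exact inverse-CDF sampler, and quadrature helpers used as independent
cross-checks by the test-suite.

Frequencies are stored as the B-allele frequency on the full symmetric
support; no folding to the minor allele is performed (sigma^2 is symmetric
about f = 0.5, so moments are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import integrate
from scipy.special import expit, logit

__all__ = [
    "FreqDistribution",
    "density",
    "cdf",
    "sample_freqs",
    "expected_inv_variance",
    "expected_inv_variance_quadrature",
    "expected_variance_uniform",
    "expected_variance_quadrature",
    "read_freqs",
    "write_freqs",
]

_KINDS = ("uniform", "ushape")


@dataclass(frozen=True)
class FreqDistribution:
    """An allele-frequency law on [f_min, 1 - f_min].

    Parameters
    ----------
    kind : {"uniform", "ushape"}
    f_min : float
        Minimum minor allele frequency, strictly inside (0, 0.5).  A lower
        bound of the form 1/(2*Ne) can be passed directly as ``f_min``.
    """

    kind: str
    f_min: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (0.0 < self.f_min < 0.5):
            raise ValueError(
                f"f_min must lie strictly in (0, 0.5), got {self.f_min!r} "
                "(f_min = 0 makes E[1/sigma^2] diverge)"
            )

    @property
    def support(self) -> tuple[float, float]:
        return (self.f_min, 1.0 - self.f_min)

    @property
    def log_odds(self) -> float:
        """log((1 - f_min)/f_min), the recurring normalisation constant."""
        return float(np.log((1.0 - self.f_min) / self.f_min))

    @property
    def norm_const(self) -> float:
        """C such that the ushape density is C/(2 f (1-f)); 1 for uniform."""
        if self.kind == "ushape":
            return 1.0 / self.log_odds
        return 1.0


def _check_support(dist: FreqDistribution, f: np.ndarray) -> None:
    lo, hi = dist.support
    if np.any(f < lo) or np.any(f > hi):
        raise ValueError(f"frequency outside support [{lo}, {hi}]")


def density(dist: FreqDistribution, f) -> np.ndarray | float:
    """Probability density of the law at ``f`` (scalar or array)."""
    f_arr = np.asarray(f, dtype=float)
    _check_support(dist, f_arr)
    if dist.kind == "uniform":
        out = np.full_like(f_arr, 1.0 / (1.0 - 2.0 * dist.f_min))
    else:
        out = dist.norm_const / (2.0 * f_arr * (1.0 - f_arr))
    return out if out.ndim else float(out)


def cdf(dist: FreqDistribution, f) -> np.ndarray | float:
    """Cumulative distribution function at ``f``."""
    f_arr = np.asarray(f, dtype=float)
    _check_support(dist, f_arr)
    if dist.kind == "uniform":
        out = (f_arr - dist.f_min) / (1.0 - 2.0 * dist.f_min)
    else:
        # integral of C/(2 f (1-f)) is (C/2) log(f/(1-f))
        out = 0.5 * dist.norm_const * (logit(f_arr) - logit(dist.f_min))
    return out if out.ndim else float(out)


def sample_freqs(dist: FreqDistribution, M: int, seed) -> np.ndarray:
    """Draw ``M`` frequencies by inverse-CDF transform.

    ``seed`` may be an int, a SeedSequence, or a Generator; a fixed seed
    yields a bit-identical vector.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(M)
    if dist.kind == "uniform":
        return dist.f_min + u * (1.0 - 2.0 * dist.f_min)
    # invert (C/2)(logit(f) - logit(f_min)) = u  via the logistic function
    return expit(logit(dist.f_min) + 2.0 * u * dist.log_odds)


def expected_inv_variance(dist: FreqDistribution) -> float:
    """Closed-form E[1/(2 f (1-f))] under the law.

    uniform : log((1-f_min)/f_min) / (1 - 2 f_min)
    ushape  : 1 + (1 - 2 f_min) / (2 f_min (1-f_min) log((1-f_min)/f_min))
    """
    a = dist.f_min
    L = dist.log_odds
    if dist.kind == "uniform":
        return L / (1.0 - 2.0 * a)
    return 1.0 + (1.0 - 2.0 * a) / (2.0 * a * (1.0 - a) * L)


def expected_inv_variance_quadrature(dist: FreqDistribution) -> float:
    """Quadrature evaluation of E[1/(2 f (1-f))]; independent cross-check."""
    lo, hi = dist.support
    val, _ = integrate.quad(
        lambda f: density(dist, f) / (2.0 * f * (1.0 - f)), lo, hi,
        epsabs=1e-12, epsrel=1e-12,
    )
    return val


def expected_variance_uniform(f_min: float) -> float:
    """The published constant behind the single-prior shrinkage ratio.

    Returns (1 - 6 f_min^2 + 2 f_min^3) / (3 (1 - 2 f_min)).  Direct
    integration of 2 f (1-f) over the uniform support gives
    (1 - 6 f_min^2 + 4 f_min^3) / (3 (1 - 2 f_min)) instead — an O(f_min^3)
    discrepancy.  The published constant is implemented verbatim here so the
    single-prior predictor matches its source; :func:`expected_variance_quadrature`
    exposes the exact integral separately.
    """
    if not (0.0 < f_min < 0.5):
        raise ValueError("f_min must lie strictly in (0, 0.5)")
    return (1.0 - 6.0 * f_min**2 + 2.0 * f_min**3) / (3.0 * (1.0 - 2.0 * f_min))


def expected_variance_quadrature(dist: FreqDistribution) -> float:
    """Quadrature evaluation of E[2 f (1-f)] under the law."""
    lo, hi = dist.support
    val, _ = integrate.quad(
        lambda f: density(dist, f) * 2.0 * f * (1.0 - f), lo, hi,
        epsabs=1e-12, epsrel=1e-12,
    )
    return val


def read_freqs(path: str | Path) -> np.ndarray:
    """Read a frequency vector: one decimal fraction per line, '#' comments."""
    vals: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals.append(float(line))
    arr = np.asarray(vals, dtype=float)
    if arr.size and (arr.min() <= 0.0 or arr.max() >= 1.0):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    return arr


def write_freqs(path: str | Path, freqs: Iterable[float]) -> None:
    with open(path, "w") as fh:
        for f in freqs:
            fh.write(f"{f:.10g}\n")
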