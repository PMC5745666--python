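"""Multivariate generalisation: first-order variance of the GEBV vector and
the precision of a linear selection index gamma = a'g."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .closed_form import PrecisionEstimate

__all__ = [
    "MultiTraitDesign",
    "gebv_variance_multitrait",
    "index_precision",
    "load_multitrait_config",
]

_SYM_TOL = 1e-12


def _check_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{name} is not symmetric to {_SYM_TOL}")
    if np.min(eigh(mat, eigvals_only=True)) <= 0.0:
        raise ValueError(f"{name} is not positive-definite")
    return mat


@dataclass(frozen=True)
class MultiTraitDesign:
    """Design of a multi-trait genomic evaluation.

    Vg, Ve : genetic / residual covariance matrices (n_traits x n_traits,
    symmetric positive-definite); a : economic weights; N, M as single-trait.
    """

    Vg: np.ndarray
    Ve: np.ndarray
    a: np.ndarray
    N: int
    M: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "Vg", _check_spd(self.Vg, "Vg"))
        object.__setattr__(self, "Ve", _check_spd(self.Ve, "Ve"))
        a = np.asarray(self.a, dtype=float).ravel()
        if a.size != self.Vg.shape[0]:
            raise ValueError(f"a has length {a.size}, expected {self.Vg.shape[0]}")
        if not np.any(a):
            raise ValueError("economic weights must not all be zero")
        if self.Vg.shape != self.Ve.shape:
            raise ValueError("Vg and Ve must have the same shape")
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be >= 1")
        object.__setattr__(self, "a", a)

    @property
    def n_traits(self) -> int:
        return self.Vg.shape[0]


def gebv_variance_multitrait(design: MultiTraitDesign) -> np.ndarray:
    """First-order GEBV covariance N Vg (N Vg + M Ve)^-1 Vg.

    Solved via a symmetric factorisation of N Vg + M Ve (no explicit
    inverse); the result is symmetrised to machine precision and satisfies
    0 <= result <= Vg in the Loewner order.
    """
    A = design.N * design.Vg + design.M * design.Ve
    sol = cho_solve(cho_factor(A, lower=True), design.Vg)
    out = design.N * design.Vg @ sol
    return 0.5 * (out + out.T)


def index_precision(design: MultiTraitDesign) -> PrecisionEstimate:
    """Precision of the selection index: (a' Vhat a) / (a' Vg a).

    Uses the best-linear-predictor identity cov(gamma, gamma_hat) =
    v(gamma_hat), which collapses cov^2/(v v_hat) to v_hat/v.
    """
    v_hat = gebv_variance_multitrait(design)
    num = float(design.a @ v_hat @ design.a)
    den = float(design.a @ design.Vg @ design.a)
    return PrecisionEstimate(num / den, "eq10_index")


def load_multitrait_config(path: str | Path) -> MultiTraitDesign:
    """Read a design from a small sectioned text file.

    Format: ``[Vg]`` / ``[Ve]`` / ``[a]`` section headers followed by
    comma-separated rows, plus ``N: <int>`` and ``M: <int>`` lines; '#'
    starts a comment.
    """
    sections: dict[str, list[list[float]]] = {}
    scalars: dict[str, int] = {}
    current: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            sections[current] = []
        elif line[:2] in ("N:", "M:"):
            key, val = (part.strip() for part in line.split(":", 1))
            scalars[key] = int(val)
        else:
            if current is None:
                raise ValueError(f"row outside any section: {raw!r}")
            sections[current].append([float(x) for x in line.split(",")])
    missing = {"Vg", "Ve", "a"} - set(sections) | {"N", "M"} - set(scalars)
    if missing:
        raise ValueError(f"config missing: {sorted(missing)}")
    return MultiTraitDesign(
        Vg=np.array(sections["Vg"]),
        Ve=np.array(sections["Ve"]),
        a=np.array(sections["a"]).ravel(),
        N=scalars["N"],
        M=scalars["M"],
    )
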