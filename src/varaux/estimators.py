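"""Point estimators of the finite-population variance Sy^2.

Each estimator consumes a drawn SRSWOR sample (as a :class:`SampleFrame`)
plus the known population variances of the auxiliary variable and/or its
ranks.  Coefficient-bearing estimators take their tuning constants
explicitly; optimal values are produced by :mod:`varaux.theory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampleFrame",
    "CoefficientSet",
    "est_usual",
    "est_ratio",
    "est_difference",
    "est_rao",
    "est_exp_ratio",
    "est_grover_kaur",
    "est_ahmad",
    "est_proposed",
    "ESTIMATOR_IDS",
]

#: Canonical estimator identifiers, in report order.
ESTIMATOR_IDS = (
    "usual", "ratio", "difference", "rao",
    "exp_ratio", "grover_kaur", "ahmad", "proposed",
)


@dataclass(frozen=True)
class SampleFrame:
    """An SRSWOR sample: unit values and their divisor-(n-1) variances.

    ``rank_x`` carries the *population* ranks of the sampled units, so the
    sample rank variance estimates the population rank variance.
    """

    y: np.ndarray
    x: np.ndarray
    rank_x: np.ndarray
    n: int
    sy2: float
    sx2: float
    srx2: float

    @classmethod
    def from_units(cls, y, x, rank_x) -> "SampleFrame":
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        rank_x = np.asarray(rank_x, dtype=float)
        if not (len(y) == len(x) == len(rank_x)):
            raise ValueError("sample vectors must have equal length")
        if len(y) < 2:
            raise ValueError("sample size must be at least 2")
        return cls(
            y=y, x=x, rank_x=rank_x, n=len(y),
            sy2=float(np.var(y, ddof=1)),
            sx2=float(np.var(x, ddof=1)),
            srx2=float(np.var(rank_x, ddof=1)),
        )


@dataclass(frozen=True)
class CoefficientSet:
    """Tuning constants for the coefficient-bearing estimators.

    Only the fields relevant to a given estimator are populated; the rest
    stay NaN.  ``provenance`` records how the values were obtained:
    ``closed_form_printed`` (reproducible from a MomentSet via the published
    closed forms), ``exact_minimization`` (solving the first-order MSE
    quadratic exactly), or ``user_supplied``.
    """

    provenance: str
    psi11: float = float("nan")
    w1: float = float("nan")
    w2: float = float("nan")
    w3: float = float("nan")
    w4: float = float("nan")
    w5: float = float("nan")
    w6: float = float("nan")
    w7: float = float("nan")
    w8: float = float("nan")
    w9: float = float("nan")
    w10: float = float("nan")

    def __post_init__(self) -> None:
        if self.provenance not in ("closed_form_printed", "exact_minimization", "user_supplied"):
            raise ValueError(f"unknown coefficient provenance: {self.provenance!r}")


def _exp_damp(S2: float, s2: float) -> float:
    """exp{(S^2 - s^2)/(S^2 + s^2)}, the exponential damping factor."""
    denom = S2 + s2
    if denom <= 0:
        raise ValueError("non-positive variance sum in exponential factor")
    return math.exp((S2 - s2) / denom)


def est_usual(s: SampleFrame) -> float:
    """The unadjusted sample variance sy^2 (design-unbiased under SRSWOR)."""
    return s.sy2


def est_ratio(s: SampleFrame, Sx2: float) -> float:
    """Ratio estimator sy^2 * (Sx^2 / sx^2)."""
    if s.sx2 <= 0:
        raise ValueError("sample auxiliary variance is zero; ratio undefined")
    return s.sy2 * Sx2 / s.sx2


def est_difference(s: SampleFrame, Sx2: float, psi11: float) -> float:
    """Difference (regression-type) estimator sy^2 + psi11 (Sx^2 - sx^2)."""
    return s.sy2 + psi11 * (Sx2 - s.sx2)


def est_rao(s: SampleFrame, Sx2: float, w1: float, w2: float) -> float:
    """Difference-type estimator w1 sy^2 + w2 (Sx^2 - sx^2)."""
    return w1 * s.sy2 + w2 * (Sx2 - s.sx2)


def est_exp_ratio(s: SampleFrame, Sx2: float) -> float:
    """Exponential-ratio estimator sy^2 * exp{(Sx^2 - sx^2)/(Sx^2 + sx^2)}."""
    return s.sy2 * _exp_damp(Sx2, s.sx2)


def est_grover_kaur(s: SampleFrame, Sx2: float, w3: float, w4: float) -> float:
    """Regression-exponential estimator
    [w3 sy^2 + w4 (Sx^2 - sx^2)] exp{(Sx^2 - sx^2)/(Sx^2 + sx^2)}."""
    return (w3 * s.sy2 + w4 * (Sx2 - s.sx2)) * _exp_damp(Sx2, s.sx2)


def est_ahmad(
    s: SampleFrame, Sx2: float, Srx2: float, w5: float, w6: float, w7: float
) -> float:
    """Dual-auxiliary regression-exponential estimator
    [w5 sy^2 + w6 (Sx^2 - sx^2) + w7 (Srx^2 - srx^2)] exp{(Sx^2 - sx^2)/(Sx^2 + sx^2)}."""
    core = w5 * s.sy2 + w6 * (Sx2 - s.sx2) + w7 * (Srx2 - s.srx2)
    return core * _exp_damp(Sx2, s.sx2)


def est_proposed(
    s: SampleFrame, Sx2: float, Srx2: float, w8: float, w9: float, w10: float
) -> float:
    """Ratio-in-regression exponential estimator with dual auxiliary terms:

    w8 sy^2 + w9 (Sx^2 - sx^2) exp{(Sx^2 - sx^2)/(Sx^2 + sx^2)}
            + w10 (Srx^2 - srx^2) exp{(Srx^2 - srx^2)/(Srx^2 + srx^2)}

    The leading term uses the *sample* variance sy^2: the alternative reading
    with the population variance would make the estimator non-stochastic in
    its leading term and contradicts the first-order expansion that defines
    its MSE.
    """
    return (
        w8 * s.sy2
        + w9 * (Sx2 - s.sx2) * _exp_damp(Sx2, s.sx2)
        + w10 * (Srx2 - s.srx2) * _exp_damp(Srx2, s.srx2)
    )
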