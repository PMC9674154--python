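"""Population-level moments for design-based variance estimation.

Everything downstream (closed-form MSEs, optimal coefficients, efficiency
comparisons) is a function of a small set of population summaries: the
variances of the study variable ``y``, the auxiliary variable ``x`` and the
ranks of ``x``, together with a grid of standardized fourth-order moment
ratios.  This module computes those summaries from raw unit-level data, or
accepts them directly as pre-computed parameters.

Conventions
-----------
* All population variances use divisor ``N - 1``.
* Ranks are on the ``1..N`` scale; ties receive average ranks, so the rank
  sum is always ``N (N + 1) / 2``.
* The mixed central moment of order ``(r, s, t)`` is

  .. math:: \\upsilon_{rst} = \\frac{1}{N-1} \\sum_i
            (y_i - \\bar Y)^r (x_i - \\bar X)^s (r_{xi} - \\bar R_x)^t

  and the scale-free moment ratio is
  ``lam_rst = v_rst / (v200^(r/2) v020^(s/2) v002^(t/2))``; the "starred"
  versions are ``lam_rst - 1`` and are what every first-order MSE consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PopulationFrame",
    "DesignSpec",
    "MomentSet",
    "rank_auxiliary",
    "sampling_factor",
    "central_moment",
    "moment_ratio",
    "summarize",
]

# Printed parameter blocks round the sampling factor to ~7 significant
# digits; DesignSpec accepts an explicit lam within this tolerance of
# 1/n - 1/N so such blocks validate.
_LAM_CONSISTENCY_RTOL = 1e-4


def rank_auxiliary(x) -> np.ndarray:
    """Rank a vector on the 1..N scale with average-rank tie handling.

    The output always sums to ``N (N + 1) / 2``; for tie-free input it is a
    permutation of ``1..N``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("auxiliary vector must be a non-empty 1-d array")
    if not np.all(np.isfinite(x)):
        raise ValueError("auxiliary vector contains non-finite values")
    return rankdata(x, method="average")


def sampling_factor(N: int, n: int) -> float:
    """First-order design factor ``1/n - 1/N`` for SRSWOR of n from N."""
    if n < 2 or n >= N:
        raise ValueError(f"invalid design: need 2 <= n < N, got n={n}, N={N}")
    return 1.0 / n - 1.0 / N


@dataclass(frozen=True)
class DesignSpec:
    """A without-replacement design: population size, sample size, and the
    sampling factor ``lam = 1/n - 1/N``."""

    N: int
    n: int
    lam: float

    def __post_init__(self) -> None:
        if self.n < 2 or self.n >= self.N:
            raise ValueError(f"invalid design: need 2 <= n < N, got n={self.n}, N={self.N}")
        if not self.lam > 0:
            raise ValueError("sampling factor must be strictly positive")
        exact = sampling_factor(self.N, self.n)
        if abs(self.lam - exact) > _LAM_CONSISTENCY_RTOL * exact:
            raise ValueError(
                f"lam={self.lam} inconsistent with 1/n - 1/N = {exact} for N={self.N}, n={self.n}"
            )

    @classmethod
    def from_sizes(cls, N: int, n: int) -> "DesignSpec":
        return cls(N=int(N), n=int(n), lam=sampling_factor(N, n))


@dataclass(frozen=True)
class PopulationFrame:
    """Unit-level population data: study variable, auxiliary variable, and
    the population ranks of the auxiliary variable."""

    y: np.ndarray
    x: np.ndarray
    rank_x: np.ndarray

    def __post_init__(self) -> None:
        for name in ("y", "x", "rank_x"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1:
                raise ValueError(f"{name} must be 1-dimensional")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if not (len(self.y) == len(self.x) == len(self.rank_x)):
            raise ValueError("y, x and rank_x must have equal length")
        if len(self.y) < 3:
            raise ValueError("population must contain at least 3 units")
        N = len(self.y)
        if not np.isclose(self.rank_x.sum(), N * (N + 1) / 2):
            raise ValueError("rank_x must sum to N(N+1)/2 (1..N ranking scale)")

    @classmethod
    def from_xy(cls, y, x) -> "PopulationFrame":
        """Build a frame from raw (y, x) pairs, computing ranks internally."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        return cls(y=y, x=x, rank_x=rank_auxiliary(x))

    @property
    def N(self) -> int:
        return len(self.y)


def central_moment(pop: PopulationFrame, r: int, s: int, t: int) -> float:
    """Mixed central moment v_rst with divisor ``N - 1``.

    ``central_moment(pop, 2, 0, 0)`` is the population variance of y.
    """
    if r < 0 or s < 0 or t < 0 or r + s + t < 1:
        raise ValueError("moment orders must be non-negative with r + s + t >= 1")
    N = pop.N
    if N < 2:
        raise ValueError("need at least 2 units for a divisor N-1 moment")
    dy = pop.y - pop.y.mean()
    dx = pop.x - pop.x.mean()
    dr = pop.rank_x - pop.rank_x.mean()
    return float(np.sum(dy**r * dx**s * dr**t) / (N - 1))


def moment_ratio(pop: PopulationFrame, r: int, s: int, t: int) -> float:
    """Scale-free moment ratio lam_rst = v_rst / (v200^(r/2) v020^(s/2) v002^(t/2)).

    Invariant under separate affine rescaling of each variable.  Requires all
    three second moments to be strictly positive.
    """
    v200 = central_moment(pop, 2, 0, 0)
    v020 = central_moment(pop, 0, 2, 0)
    v002 = central_moment(pop, 0, 0, 2)
    if min(v200, v020, v002) <= 0:
        raise ValueError("degenerate population: a second moment is zero")
    v = central_moment(pop, r, s, t)
    return v / (v200 ** (r / 2) * v020 ** (s / 2) * v002 ** (t / 2))


@dataclass(frozen=True)
class MomentSet:
    """All population summaries needed by the closed-form theory.

    ``lam***`` are raw moment ratios; ``lam***s`` the starred (minus one)
    versions.  ``rho_star`` is the moment-ratio correlation
    ``lam220s / sqrt(lam400s * lam040s)`` used by the difference estimator.
    """

    Sy2: float
    Sx2: float
    Srx2: float
    lam400: float
    lam040: float
    lam004: float
    lam220: float
    lam202: float
    lam022: float
    lam400s: float
    lam040s: float
    lam004s: float
    lam220s: float
    lam202s: float
    lam022s: float
    rho_star: float
    mean_y: float = float("nan")
    mean_x: float = float("nan")
    mean_rx: float = float("nan")
    rho_yx: float = float("nan")
    rho_yrx: float = float("nan")
    rho_xrx: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.Sy2, self.Sx2, self.Srx2) <= 0:
            raise ValueError("population variances must be strictly positive")
        for base in ("400", "040", "004", "220", "202", "022"):
            raw = getattr(self, f"lam{base}")
            star = getattr(self, f"lam{base}s")
            if not np.isclose(star, raw - 1.0, rtol=0, atol=1e-9):
                raise ValueError(f"lam{base}s must equal lam{base} - 1")
        for name in ("rho_yx", "rho_yrx", "rho_xrx"):
            r = getattr(self, name)
            if np.isfinite(r) and abs(r) > 1 + 1e-12:
                raise ValueError(f"{name} must lie in [-1, 1]")

    @classmethod
    def from_starred(
        cls,
        *,
        Sy2: float,
        Sx2: float,
        Srx2: float,
        lam400s: float,
        lam040s: float,
        lam004s: float,
        lam220s: float,
        lam202s: float,
        lam022s: float,
        **extra: float,
    ) -> "MomentSet":
        """Construct directly from printed parameters (starred ratios)."""
        starred = dict(
            lam400s=lam400s, lam040s=lam040s, lam004s=lam004s,
            lam220s=lam220s, lam202s=lam202s, lam022s=lam022s,
        )
        raw = {k[:-1]: v + 1.0 for k, v in starred.items()}
        rho_star = lam220s / np.sqrt(lam400s * lam040s)
        return cls(
            Sy2=Sy2, Sx2=Sx2, Srx2=Srx2,
            rho_star=float(rho_star), **raw, **starred, **extra,
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def summarize(pop: PopulationFrame, design: DesignSpec | None = None) -> MomentSet:
    """Aggregate a population frame into a :class:`MomentSet`.

    The design is accepted for interface symmetry but no field of the result
    depends on it; pass ``None`` when only moments are needed.
    """
    if design is not None and design.N != pop.N:
        raise ValueError(f"design N={design.N} does not match population N={pop.N}")
    ratios = {}
    for base in ("400", "040", "004", "220", "202", "022"):
        r, s, t = (int(c) for c in base)
        ratios[f"lam{base}"] = moment_ratio(pop, r, s, t)
    starred = {f"{k}s": v - 1.0 for k, v in ratios.items()}
    return MomentSet(
        Sy2=central_moment(pop, 2, 0, 0),
        Sx2=central_moment(pop, 0, 2, 0),
        Srx2=central_moment(pop, 0, 0, 2),
        mean_y=float(pop.y.mean()),
        mean_x=float(pop.x.mean()),
        mean_rx=float(pop.rank_x.mean()),
        rho_yx=_pearson(pop.y, pop.x),
        rho_yrx=_pearson(pop.y, pop.rank_x),
        rho_xrx=_pearson(pop.x, pop.rank_x),
        rho_star=float(starred["lam220s"] / np.sqrt(starred["lam400s"] * starred["lam040s"])),
        **ratios,
        **starred,
    )
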