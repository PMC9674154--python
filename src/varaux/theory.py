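"""First-order (delta-method) bias, MSE and PRE for all eight estimators.

Every function here is a closed form in a :class:`~varaux.moments.MomentSet`
and a :class:`~varaux.moments.DesignSpec`; nothing touches unit-level data.

Two routes are provided for the proposed dual-auxiliary estimator:

* :func:`mse_proposed_exact` — the authoritative value: the first-order MSE
  is an exact quadratic in the three coefficients, and this solves the 3x3
  stationarity system.
* :func:`mse_proposed_printed` — the literal published minimum-MSE closed
  form, which is inconsistent with its own quadratic (it can be negative
  where the quadratic minimum is positive) and is therefore exposed only
  with a warning flag.

Prefactor conventions: the published Grover-Kaur and dual-auxiliary minimum
MSEs carry an Sy^2 prefactor, which is dimensionally impossible for a
variance-of-variance; Sy^4 is used throughout.  With Sy^4 both closed forms
agree to machine precision with the exact quadratic minima of their own
expansions, which is the internal consistency check the test suite enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import CoefficientSet
from .moments import DesignSpec, MomentSet

__all__ = [
    "TheoryResult",
    "AuxScalars",
    "pre_of",
    "var_usual",
    "mse_ratio",
    "var_difference",
    "mse_rao",
    "mse_exp_ratio",
    "mse_grover_kaur",
    "gamma_star",
    "mse_ahmad",
    "aux_scalars",
    "proposed_mse_at",
    "mse_proposed_exact",
    "mse_proposed_printed",
    "proposed_coefficients_printed",
    "optimal_coefficients",
    "scaled_bias_table",
    "theory_table",
]

FLAG_PRINTED_FORM_INCONSISTENT = "printed-minimum-formula-inconsistent"
FLAG_NEGATIVE_FIRST_ORDER_MIN = "negative-first-order-minimum"


@dataclass(frozen=True)
class TheoryResult:
    """First-order bias/MSE/PRE of one estimator on one population."""

    estimator_id: str
    bias: float
    mse: float
    pre: float
    coefficients: CoefficientSet | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AuxScalars:
    """Scalar combinations of the starred moment ratios used by the printed
    optimum coefficients and the pairwise efficiency conditions."""

    gamma_star: float
    y1: float
    n1: float
    y11: float
    n11: float
    m_threshold: float


def pre_of(mse: float, var0: float) -> float:
    """Percentage relative efficiency, 100 * Var(usual) / MSE."""
    if mse == 0:
        raise ValueError("zero MSE: PRE undefined")
    if var0 <= 0:
        raise ValueError("reference variance must be positive")
    return 100.0 * var0 / mse


def _unpack(m: MomentSet):
    return (m.lam400s, m.lam040s, m.lam004s, m.lam220s, m.lam202s, m.lam022s)


def var_usual(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Variance of the unadjusted sample variance: lam * Sy^4 * lam400s."""
    mse = d.lam * m.Sy2**2 * m.lam400s
    return TheoryResult("usual", bias=float("nan"), mse=mse, pre=100.0)


def mse_ratio(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Ratio estimator: MSE = lam Sy^4 (lam400s + lam040s - 2 lam220s)."""
    L400, L040, _, L220, _, _ = _unpack(m)
    Sy4 = m.Sy2**2
    mse = d.lam * Sy4 * (L400 + L040 - 2 * L220)
    bias = d.lam * m.Sy2 * (L040 - L220)
    return TheoryResult("ratio", bias=bias, mse=mse, pre=_pre(m, d, mse))


def var_difference(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Difference estimator at its optimal coefficient:
    Var = lam Sy^4 lam400s (1 - rho_star^2)."""
    L400, L040, _, L220, _, _ = _unpack(m)
    if L040 <= 0 or L400 <= 0:
        raise ValueError("degenerate moment ratios for the difference estimator")
    rho = m.rho_star
    mse = d.lam * m.Sy2**2 * L400 * (1 - rho**2)
    psi11 = m.Sy2 * L220 / (m.Sx2 * L040)
    coeffs = CoefficientSet(provenance="closed_form_printed", psi11=psi11)
    return TheoryResult("difference", bias=float("nan"), mse=mse,
                        pre=_pre(m, d, mse), coefficients=coeffs)


def mse_rao(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Two-coefficient difference-type estimator at its optimum:
    MSE = lam Sy^4 A / (lam A + lam040s), A = lam400s lam040s - lam220s^2."""
    L400, L040, _, L220, _, _ = _unpack(m)
    A = L400 * L040 - L220**2
    denom = d.lam * A + L040
    if denom <= 0:
        raise ValueError("degenerate denominator in difference-type MSE")
    mse = d.lam * m.Sy2**2 * A / denom
    w1 = L040 / denom
    w2 = m.Sy2 * L220 / (m.Sx2 * denom)
    bias = m.Sy2 * (w1 - 1.0)
    coeffs = CoefficientSet(provenance="closed_form_printed", w1=w1, w2=w2)
    return TheoryResult("rao", bias=bias, mse=mse, pre=_pre(m, d, mse),
                        coefficients=coeffs)


def mse_exp_ratio(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Exponential-ratio estimator:
    MSE = lam Sy^4 (lam400s + lam040s/4 - lam220s)."""
    L400, L040, _, L220, _, _ = _unpack(m)
    Sy4 = m.Sy2**2
    mse = d.lam * Sy4 * (L400 + L040 / 4 - L220)
    bias = d.lam * m.Sy2 * (3 * L040 / 8 - L220 / 2)
    return TheoryResult("exp_ratio", bias=bias, mse=mse, pre=_pre(m, d, mse))


def mse_grover_kaur(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Regression-exponential estimator at its optimum coefficients:

    MSE = lam Sy^4 [64 A - lam lam040s^3 - 16 lam lam040s A]
          / (64 [lam A + lam040s]),   A = lam400s lam040s - lam220s^2.
    """
    L400, L040, _, L220, _, _ = _unpack(m)
    lam = d.lam
    A = L400 * L040 - L220**2
    denom = lam * A + L040
    if denom <= 0:
        raise ValueError("degenerate denominator in regression-exponential MSE")
    mse = lam * m.Sy2**2 * (64 * A - lam * L040**3 - 16 * lam * L040 * A) / (64 * denom)
    w3 = (8 * L040 - lam * L040**2) / (8 * denom)
    w4 = m.Sy2 * (
        lam * L040**2 - lam * L040 * L220 + 8 * L220 - 4 * (L040 - lam * A)
    ) / (8 * m.Sx2 * denom)
    bias = (
        -m.Sy2
        + w3 * m.Sy2 * (1 + lam * (3 * L040 / 8 - L220 / 2))
        + 0.5 * w4 * m.Sx2 * lam * L040
    )
    coeffs = CoefficientSet(provenance="closed_form_printed", w3=w3, w4=w4)
    return TheoryResult("grover_kaur", bias=bias, mse=mse, pre=_pre(m, d, mse),
                        coefficients=coeffs)


def gamma_star(m: MomentSet) -> float:
    """Gamma-star scalar of the dual-auxiliary minimum MSE:

    (2 lam220s lam202s lam022s - lam040s lam202s^2 - lam004s lam220s^2)
    / (lam400s (lam040s lam004s - lam022s^2))

    The published text prints the denominator both with lam220s^2 and with
    lam022s^2; the lam022s^2 reading is used because it is the determinant of
    the auxiliary block of the error-term covariance and it reproduces the
    published minimum-MSE table for the dual-auxiliary estimator.
    """
    L400, L040, L004, L220, L202, L022 = _unpack(m)
    det_aux = L040 * L004 - L022**2
    if L400 <= 0 or det_aux == 0:
        raise ValueError("singular denominator in gamma_star")
    num = 2 * L220 * L202 * L022 - L040 * L202**2 - L004 * L220**2
    return num / (L400 * det_aux)


def _ahmad_quadratic_system(m: MomentSet, d: DesignSpec):
    """First-order MSE of the dual-auxiliary estimator as a function of
    (w5, w6, w7); an exact quadratic.

    Derived from the first-order expansion of
    [w5 sy^2 + w6 (Sx^2-sx^2) + w7 (Srx^2-srx^2)] exp{(Sx^2-sx^2)/(Sx^2+sx^2)}:
    with a = w5 Sy^2, b = w5 Sy^2/2 + w6 Sx^2, c = w7 Srx^2,
    q = 3 w5 Sy^2/8 + w6 Sx^2/2 and C0 = (w5 - 1) Sy^2,

    MSE = C0^2 + lam (a^2 L400 + b^2 L040 + c^2 L004)
        + 2 C0 lam (q L040 - a L220 / 2 + c L022 / 2)
        - 2 lam (a b L220 + a c L202) + 2 lam b c L022.
    """
    L400, L040, L004, L220, L202, L022 = _unpack(m)
    lam, Sy2, Sx2, Srx2 = d.lam, m.Sy2, m.Sx2, m.Srx2

    def f(w: np.ndarray) -> float:
        w5, w6, w7 = w
        C0 = (w5 - 1) * Sy2
        a = w5 * Sy2
        b = w5 * Sy2 / 2 + w6 * Sx2
        c = w7 * Srx2
        q = 3 * w5 * Sy2 / 8 + w6 * Sx2 / 2
        return (
            C0**2
            + lam * (a * a * L400 + b * b * L040 + c * c * L004)
            + 2 * C0 * lam * (q * L040 - a * L220 / 2 + c * L022 / 2)
            - 2 * lam * (a * b * L220 + a * c * L202)
            + 2 * lam * b * c * L022
        )

    return f


def _minimize_quadratic(f, center, scales) -> np.ndarray:
    """Exact minimizer of an algebraically quadratic f.

    The Hessian and gradient are extracted by finite differences, which are
    exact for quadratics up to float rounding.  Differencing happens around
    ``center`` (the no-adjustment coefficient point, where the huge
    bias-squared constant vanishes) with per-coordinate ``scales`` (the
    natural variance ratios), so all probed values share the lam * Sy^4
    magnitude and no catastrophic cancellation occurs even for tiny sampling
    factors.
    """
    c = np.asarray(center, dtype=float)
    D = np.asarray(scales, dtype=float)
    dim = len(c)

    def F(u: np.ndarray) -> float:
        return f(c + D * u)

    e = np.eye(dim)
    F0 = F(np.zeros(dim))
    g = np.zeros(dim)
    H = np.zeros((dim, dim))
    for i in range(dim):
        fp, fm = F(e[i]), F(-e[i])
        g[i] = (fp - fm) / 2
        H[i, i] = fp + fm - 2 * F0
    for i in range(dim):
        for j in range(i + 1, dim):
            H[i, j] = H[j, i] = F(e[i] + e[j]) - F(e[i]) - F(e[j]) + F0

    diag = np.diag(H)
    if np.any(diag <= 0):
        raise ValueError("first-order MSE quadratic is not positive definite")
    s = 1.0 / np.sqrt(diag)
    Hs = H * np.outer(s, s)
    try:
        np.linalg.cholesky(Hs)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(Hs)
        raise ValueError(
            f"first-order MSE quadratic is not positive definite "
            f"(scaled condition number {cond:.3e}); no finite minimum"
        )
    u = s * np.linalg.solve(Hs, -(s * g))
    return c + D * u


def mse_ahmad(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Dual-auxiliary regression-exponential estimator at its optimum:

    MSE_min = lam Sy^4 [64 (G+1) - lam lam040s^2 / lam400s
              - 16 lam lam040s (G+1)] / (64 [1/lam400s + lam (G+1)])

    with G = gamma_star.  Coefficients are populated from the exact 3x3
    minimization of the underlying quadratic (the published w6/w7 closed
    forms are too garbled to evaluate; w5 matches its published closed form
    and the quadratic minimum matches this closed-form MSE, which the test
    suite asserts).
    """
    L400, L040, _, _, _, _ = _unpack(m)
    lam = d.lam
    G = gamma_star(m)
    denom = 1.0 / L400 + lam * (G + 1.0)
    if denom <= 0:
        raise ValueError("degenerate denominator in dual-auxiliary MSE")
    mse = lam * m.Sy2**2 * (
        64 * (G + 1) - lam * L040**2 / L400 - 16 * lam * L040 * (G + 1)
    ) / (64 * denom)
    f = _ahmad_quadratic_system(m, d)
    w5, w6, w7 = _minimize_quadratic(
        f, center=(1.0, 0.0, 0.0), scales=(1.0, m.Sy2 / m.Sx2, m.Sy2 / m.Srx2))
    L220 = m.lam220s
    L022 = m.lam022s
    bias = (
        -m.Sy2
        + w5 * m.Sy2 * (1 + lam * (3 * L040 / 8 - L220 / 2))
        + 0.5 * lam * (w6 * m.Sx2 * L040 + w7 * m.Srx2 * L022)
    )
    coeffs = CoefficientSet(provenance="exact_minimization", w5=w5, w6=w6, w7=w7)
    return TheoryResult("ahmad", bias=bias, mse=mse, pre=_pre(m, d, mse),
                        coefficients=coeffs)


def aux_scalars(m: MomentSet, d: DesignSpec) -> AuxScalars:
    """Scalars of the printed proposed-estimator optimum, all sharing the
    denominator lam040s lam004s - lam022s^2 (times lam400s where printed)."""
    L400, L040, L004, L220, L202, L022 = _unpack(m)
    det_aux = L040 * L004 - L022**2
    if L400 <= 0 or det_aux == 0:
        raise ValueError("singular shared denominator in auxiliary scalars")
    G = gamma_star(m)
    y1 = (L202 * L040 - L004 * L220) ** 2 / (L400 * det_aux)
    n1 = L040 * L004 * (L040 + L004 - 2 * L022) / det_aux
    y11 = L004 * L220 * (L040 - L022) / (L400 * det_aux)
    n11 = L040 * L202 * (L004 - L022) / (L400 * det_aux)
    m_threshold = ((y1 - n1) * d.lam + (G + 1)) / (
        d.lam * (4 * ((G + 1) + (y11 + n11)) - n1 * L400) + 4 * L400
    )
    return AuxScalars(gamma_star=G, y1=y1, n1=n1, y11=y11, n11=n11,
                      m_threshold=m_threshold)


def proposed_mse_at(
    m: MomentSet, d: DesignSpec, w8: float, w9: float, w10: float
) -> float:
    """First-order MSE of the proposed estimator at arbitrary coefficients.

    MSE = (w8-1)^2 Sy^4
        + lam [ w8^2 Sy^4 L400 + w9^2 Sx^4 L040 + w10^2 Srx^4 L004
              + (w8-1) w9 Sy^2 Sx^2 L040 + (w8-1) w10 Sy^2 Srx^2 L004
              - 2 w8 w9 Sy^2 Sx^2 L220 - 2 w8 w10 Sy^2 Srx^2 L202
              + 2 w9 w10 Sx^2 Srx^2 L022 ]

    The final cross term uses Sx^2 Srx^2: it multiplies the covariance of the
    x- and rank-error terms, so the published Sy^2 Srx^4 factor there is a
    typographical impossibility.
    """
    L400, L040, L004, L220, L202, L022 = _unpack(m)
    lam, Sy2, Sx2, Srx2 = d.lam, m.Sy2, m.Sx2, m.Srx2
    return (
        Sy2**2 * (w8 - 1) ** 2
        + lam
        * (
            w8**2 * Sy2**2 * L400
            + w9**2 * Sx2**2 * L040
            + w10**2 * Srx2**2 * L004
            + (w8 - 1) * w9 * Sy2 * Sx2 * L040
            + (w8 - 1) * w10 * Sy2 * Srx2 * L004
            - 2 * w8 * w9 * Sy2 * Sx2 * L220
            - 2 * w8 * w10 * Sy2 * Srx2 * L202
            + 2 * w9 * w10 * Sx2 * Srx2 * L022
        )
    )


def mse_proposed_exact(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """Exact minimum of the proposed estimator's first-order MSE quadratic.

    This is the package's authoritative MSE for the proposed estimator.  The
    quadratic surface itself is only a first-order approximation: on moment
    grids that are nearly singular in the auxiliary block its minimum can be
    negative, which is reported as-is with a flag rather than clipped.
    """
    def f(w: np.ndarray) -> float:
        return proposed_mse_at(m, d, *w)

    w8, w9, w10 = _minimize_quadratic(
        f, center=(1.0, 0.0, 0.0), scales=(1.0, m.Sy2 / m.Sx2, m.Sy2 / m.Srx2))
    mse = float(f(np.array([w8, w9, w10])))
    lam = d.lam
    bias = (w8 - 1) * m.Sy2 + 0.5 * lam * (
        w9 * m.Sx2 * m.lam040s + w10 * m.Srx2 * m.lam004s
    )
    flags = () if mse > 0 else (FLAG_NEGATIVE_FIRST_ORDER_MIN,)
    coeffs = CoefficientSet(provenance="exact_minimization", w8=w8, w9=w9, w10=w10)
    return TheoryResult("proposed", bias=bias, mse=mse, pre=_pre(m, d, mse),
                        coefficients=coeffs, flags=flags)


def mse_proposed_printed(m: MomentSet, d: DesignSpec) -> TheoryResult:
    """The published minimum-MSE closed form, evaluated literally:

    MSE_min = lam Sy^4 [(y1 - n1) lam + (G+1)]
              / (lam [4 {(G+1) + (y11 + n11)} - n1 lam400s] + 4 lam400s)

    Flagged: this expression does not agree with the exact minimum of its own
    quadratic and can be negative; it is retained for documentation and
    comparison only.
    """
    s = aux_scalars(m, d)
    mse = d.lam * m.Sy2**2 * s.m_threshold
    flags = [FLAG_PRINTED_FORM_INCONSISTENT]
    if mse <= 0:
        flags.append(FLAG_NEGATIVE_FIRST_ORDER_MIN)
    coeffs = proposed_coefficients_printed(m, d)
    bias = (coeffs.w8 - 1) * m.Sy2 + 0.5 * d.lam * (
        coeffs.w9 * m.Sx2 * m.lam040s + coeffs.w10 * m.Srx2 * m.lam004s
    )
    return TheoryResult("proposed", bias=bias, mse=mse, pre=_pre(m, d, mse),
                        coefficients=coeffs, flags=tuple(flags))


def proposed_coefficients_printed(m: MomentSet, d: DesignSpec) -> CoefficientSet:
    """The published optimum-coefficient closed forms, evaluated literally.

    Retained for documentation and comparison against the exact minimizer;
    the printed forms do not recover the exact optimum (e.g. w8 does not tend
    to 1 in the census limit).  Where the printed subscripts are internally
    inconsistent (the w8 denominator prints both n1 and n11; the w10
    denominator tail prints n1 lam400s where w9 prints 4 lam400s) the
    Eq-19-consistent reading (n1, + 4 lam400s) is used.
    """
    L400, L040, L004, L220, L202, L022 = _unpack(m)
    lam, Sy2, Sx2, Srx2 = d.lam, m.Sy2, m.Sx2, m.Srx2
    s = aux_scalars(m, d)
    G, y1, n1, y11, n11 = s.gamma_star, s.y1, s.n1, s.y11, s.n11
    det_aux = L040 * L004 - L022**2
    shared = lam * (4 * ((G + 1) + (y11 + n11)) - n1 * L400) + 4 * L400
    if shared == 0 or det_aux == 0:
        raise ValueError("zero denominator in printed optimum coefficients")
    w8 = (lam * (n1 * L400 - 2 * (y11 + n11)) - 4 * L400) / shared
    w9 = Sy2 * (
        2 * lam * L400 * L004 * (L040 - L022)
        + lam * L040 * L202 * (L004 - 2 * L202)
        + lam * L004 * L220 * (-L004 + 2 * L202)
        + 4 * (L004 * L220 - L202 * L022)
    ) / (Sx2 * L400 * det_aux * shared)
    w10 = Sy2 * (
        2 * lam * L400 * L040 * (L004 - L022)
        + lam * L040 * L202 * (-L040 + 2 * L220)
        + lam * L004 * L220 * (L040 - 2 * L220)
        + 4 * (L040 * L202 - L220 * L022)
    ) / (Srx2 * L400 * det_aux * shared)
    return CoefficientSet(provenance="closed_form_printed", w8=w8, w9=w9, w10=w10)


def _pre(m: MomentSet, d: DesignSpec, mse: float) -> float:
    # a vanishing first-order MSE is a legitimate degenerate corner of the
    # moment space; report infinite efficiency rather than erroring out
    if mse == 0:
        return float("inf")
    return pre_of(mse, var_usual(m, d).mse)


def scaled_bias_table(m: MomentSet, d: DesignSpec) -> dict[str, float]:
    """First-order bias entries on the scale the published bias table uses.

    Only the ratio and exponential-ratio rows of that table are reproducible:
    they equal Sy^2 times the natural first-order biases, i.e.
    lam Sy^4 (lam040s - lam220s) and lam Sy^4 (3 lam040s / 8 - lam220s / 2).
    All other entries are reported in natural Sy^2 units from the first-order
    bias formulas (evaluated at optimal coefficients); they do not reconcile
    with the published table under either scaling.
    """
    lam, Sy4 = d.lam, m.Sy2**2
    table: dict[str, float] = {
        "usual": float("nan"),
        "ratio": lam * Sy4 * (m.lam040s - m.lam220s),
        "difference": float("nan"),
        "rao": mse_rao(m, d).bias,
        "exp_ratio": lam * Sy4 * (3 * m.lam040s / 8 - m.lam220s / 2),
        "grover_kaur": mse_grover_kaur(m, d).bias,
        "ahmad": mse_ahmad(m, d).bias,
        "proposed": mse_proposed_exact(m, d).bias,
    }
    return table


def optimal_coefficients(m: MomentSet, d: DesignSpec) -> CoefficientSet:
    """One CoefficientSet carrying the operating coefficients of every
    estimator: closed forms where the published ones are sound, exact
    quadratic minimization for the dual-auxiliary and proposed estimators."""
    diff = var_difference(m, d).coefficients
    rao = mse_rao(m, d).coefficients
    gk = mse_grover_kaur(m, d).coefficients
    ahm = mse_ahmad(m, d).coefficients
    prop = mse_proposed_exact(m, d).coefficients
    return CoefficientSet(
        provenance="exact_minimization",
        psi11=diff.psi11, w1=rao.w1, w2=rao.w2, w3=gk.w3, w4=gk.w4,
        w5=ahm.w5, w6=ahm.w6, w7=ahm.w7, w8=prop.w8, w9=prop.w9, w10=prop.w10,
    )


def theory_table(
    m: MomentSet, d: DesignSpec, proposed_mode: str = "exact"
) -> list[TheoryResult]:
    """All eight estimators' first-order results, in report order."""
    if proposed_mode not in ("exact", "printed"):
        raise ValueError("proposed_mode must be 'exact' or 'printed'")
    proposed = mse_proposed_exact if proposed_mode == "exact" else mse_proposed_printed
    return [
        var_usual(m, d),
        mse_ratio(m, d),
        var_difference(m, d),
        mse_rao(m, d),
        mse_exp_ratio(m, d),
        mse_grover_kaur(m, d),
        mse_ahmad(m, d),
        proposed(m, d),
    ]
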