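"""Pairwise efficiency conditions of the proposed estimator.

Each condition asks whether the proposed estimator's first-order MSE is
strictly below a competitor's.  After dividing by lam * Sy^4 the published
inequalities are exactly MSE differences, so the report evaluates the
differences directly from the theory module and additionally carries the
threshold scalar M = MSE(proposed) / (lam Sy^4) from the printed closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

from .moments import DesignSpec, MomentSet
from . import theory

__all__ = ["Comparison", "EfficiencyReport", "compare_all"]

#: Competitors compared against, in the order the conditions are stated.
COMPETITOR_IDS = (
    "usual", "ratio", "difference", "rao", "exp_ratio", "grover_kaur", "ahmad",
)


@dataclass(frozen=True)
class Comparison:
    competitor_id: str
    lhs: float           # competitor first-order MSE
    rhs: float           # proposed first-order MSE
    proposed_better: bool


@dataclass(frozen=True)
class EfficiencyReport:
    comparisons: dict[str, Comparison]
    m_threshold: float
    proposed_mode: str
    flags: tuple[str, ...] = ()


def compare_all(
    m: MomentSet, d: DesignSpec, proposed_mode: str = "exact"
) -> EfficiencyReport:
    """Evaluate every pairwise condition as a strict MSE inequality.

    Ties count as not-better (the conditions are strict).  In ``printed``
    mode the proposed MSE comes from the literal published closed form and
    the report inherits its inconsistency flag.
    """
    if proposed_mode == "exact":
        prop = theory.mse_proposed_exact(m, d)
    elif proposed_mode == "printed":
        prop = theory.mse_proposed_printed(m, d)
    else:
        raise ValueError("proposed_mode must be 'exact' or 'printed'")

    results = {r.estimator_id: r for r in theory.theory_table(m, d, proposed_mode)}
    comparisons = {}
    for cid in COMPETITOR_IDS:
        lhs = results[cid].mse
        comparisons[cid] = Comparison(
            competitor_id=cid, lhs=lhs, rhs=prop.mse,
            proposed_better=bool(lhs - prop.mse > 0),
        )
    return EfficiencyReport(
        comparisons=comparisons,
        m_threshold=theory.aux_scalars(m, d).m_threshold,
        proposed_mode=proposed_mode,
        flags=prop.flags,
    )
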