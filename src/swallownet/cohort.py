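"""Cohort-level group-comparison statistics and participant-flow arithmetic.

Covers the descriptive statistics a screening study reports alongside the
model: chi-square tests on 2xk contingency tables (Yates continuity
correction for 2x2), Cohen's kappa for rater agreement, and a running
participant-flow ledger from enrollment through exclusions.

The study-population tables and flow deltas of the source cohort are
included as constants so the statistics can be recomputed from printed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import cohen_kappa_score

# Study-population contingency tables (rows: normal, aspiration).
# Sex columns: male, female. Comorbidity columns: neurological, GI/dental,
# respiratory, other-site cancer, aging-associated, none.
STUDY_SEX_TABLE = [[41, 87], [52, 18]]
STUDY_COMORBIDITY_OVERALL = [[17, 3, 4, 7, 12, 85], [18, 12, 9, 3, 8, 20]]
STUDY_COMORBIDITY_MALE = [[5, 1, 2, 2, 5, 26], [11, 12, 8, 2, 6, 13]]
STUDY_COMORBIDITY_FEMALE = [[12, 2, 2, 5, 7, 59], [7, 0, 1, 1, 2, 7]]

# Participant flow: enrollment counts then per-stage (normal, aspiration)
# deltas — age-based exclusion (<40 y), then audio-quality exclusion.
STUDY_ENROLLMENT = (212, 73)
STUDY_FLOW_STAGES = [
    ("excluded: age under 40", -78, -1),
    ("excluded: audio quality", -6, -2),
]


def chi_square(
    table: Sequence[Sequence[int]], continuity_correction: bool = False
) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom for a 2xk table.

    ``continuity_correction`` applies the Yates correction (2x2 tables only;
    it is a no-op for wider tables). Zero marginals are rejected.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D non-negative matrix")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal; expected counts undefined")
    res = chi2_contingency(t, correction=continuity_correction)
    return float(res.statistic), int(res.dof)


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Chance-corrected inter-rater agreement (p_o - p_e) / (1 - p_e)."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating sequences must have equal length")
    if len(ratings_a) == 0:
        raise ValueError("empty rating sequences")
    a = list(ratings_a)
    b = list(ratings_b)
    if len(set(a)) == 1 and a == b:
        # degenerate perfect agreement on a single category: p_e == 1
        raise ValueError("kappa undefined: chance agreement is 1")
    return float(cohen_kappa_score(a, b))


@dataclass
class FlowLedger:
    """Enrollment counts plus ordered per-stage (label, d_normal, d_aspiration)."""

    enrollment: tuple[int, int]
    stages: list[tuple[str, int, int]]


def participant_flow(ledger: FlowLedger) -> tuple[tuple[int, int], list[dict]]:
    """Apply exclusion deltas sequentially; running counts must stay >= 0.

    Returns the final (normal, aspiration) counts and the per-stage trace.
    """
    normal, aspiration = ledger.enrollment
    if normal < 0 or aspiration < 0:
        raise ValueError("enrollment counts must be non-negative")
    trace = [{"stage": "enrollment", "normal": normal, "aspiration": aspiration}]
    for label, d_norm, d_asp in ledger.stages:
        normal += d_norm
        aspiration += d_asp
        if normal < 0 or aspiration < 0:
            raise ValueError(f"negative running count after stage {label!r}")
        trace.append({"stage": label, "normal": normal, "aspiration": aspiration})
    return (normal, aspiration), trace


def study_flow_ledger() -> FlowLedger:
    """The source cohort's printed enrollment and exclusion deltas."""
    return FlowLedger(enrollment=STUDY_ENROLLMENT, stages=list(STUDY_FLOW_STAGES))
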