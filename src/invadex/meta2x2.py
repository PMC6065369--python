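"""Per-study exact odds-ratio analysis of 2x2 exposure x outcome tables.

Built for the hormone-replacement-therapy / lymph-node-dissemination
meta-analysis: each study contributes a 2x2 table of exposure (HRT
current-user vs never-user) against outcome (e.g. more than three positive
lymph nodes).  Studies with fewer than 10 patients in either treatment
group are excluded.  Each included study gets a sample odds ratio
(a*d)/(b*c), a two-sided Fisher exact p, and the conditional exact
(Cornfield-type) 95% confidence interval obtained by inverting noncentral
hypergeometric tail tests at alpha/2 per side.  An optional
Mantel-Haenszel pooled estimate is available as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "ContingencyTable2x2",
    "StudyResult",
    "filter_studies",
    "odds_ratio",
    "fisher_exact_p",
    "exact_ci",
    "forest_table",
    "mantel_haenszel_or",
]


@dataclass
class ContingencyTable2x2:
    """Counts: a = exposed & outcome+, b = exposed & outcome-,
    c = unexposed & outcome+, d = unexposed & outcome-.

    Negative counts act as missing-data sentinels; they fail validation and
    are reported as incomplete by filter_studies.
    """

    study_id: str
    a: int
    b: int
    c: int
    d: int

    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def is_complete(self) -> bool:
        return min(self.a, self.b, self.c, self.d) >= 0 and self.n > 0


@dataclass
class StudyResult:
    study_id: str
    or_point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_exact: float | None = None
    included: bool = True
    reason: str = ""
    corrected: bool = False  # 0.5 continuity correction applied to the OR


def filter_studies(tables: list[ContingencyTable2x2],
                   min_per_group: int = 10) -> list[StudyResult]:
    """Apply the study-inclusion filter: a minimum of `min_per_group`
    patients in each treatment (exposure) group, complete counts required.
    """
    out = []
    for t in tables:
        if not t.is_complete():
            out.append(StudyResult(t.study_id, included=False,
                                   reason="incomplete counts"))
        elif t.a + t.b < min_per_group:
            out.append(StudyResult(t.study_id, included=False,
                                   reason=f"exposed group < {min_per_group}"))
        elif t.c + t.d < min_per_group:
            out.append(StudyResult(t.study_id, included=False,
                                   reason=f"unexposed group < {min_per_group}"))
        else:
            out.append(StudyResult(t.study_id, included=True))
    return out


def odds_ratio(table: ContingencyTable2x2,
               continuity_correction: bool = True) -> tuple[float, bool]:
    """Sample odds ratio (a*d)/(b*c).

    If any cell is zero the Haldane-Anscombe 0.5 correction is added to all
    four cells (when enabled) and the result is flagged; with the
    correction disabled, a zero in b or c raises.

    Returns (odds_ratio, corrected_flag).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            if b * c == 0:
                raise ValueError("zero cell: OR undefined without correction")
            return a * d / (b * c), False
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed that of the observed
    table.
    """
    if not table.is_complete():
        raise ValueError("incomplete table")
    _, p = stats.fisher_exact(table.counts(), alternative="two-sided")
    return float(min(p, 1.0))


def exact_ci(table: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Conditional exact (Cornfield-type) confidence interval for the OR.

    Obtained by inverting the noncentral hypergeometric tail tests at
    (1-level)/2 per side, conditioning on both margins.  The lower bound is
    0 when a is at its conditional minimum and the upper bound infinity
    when a is at its conditional maximum.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise ValueError("degenerate margins: exact CI undefined")
    res = _scipy_odds_ratio(table.counts(), kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return float(ci.low), float(ci.high)


def study_result(table: ContingencyTable2x2, level: float = 0.95) -> StudyResult:
    """Full per-study exact analysis (OR, exact CI, Fisher p)."""
    or_point, corrected = odds_ratio(table)
    ci_low, ci_high = exact_ci(table, level=level)
    return StudyResult(
        study_id=table.study_id, or_point=or_point, ci_low=ci_low,
        ci_high=ci_high, p_exact=fisher_exact_p(table), included=True,
        corrected=corrected,
    )


def mantel_haenszel_or(tables: list[ContingencyTable2x2]) -> float:
    """Mantel-Haenszel fixed-effect pooled odds ratio across studies."""
    num = sum(t.a * t.d / t.n for t in tables)
    den = sum(t.b * t.c / t.n for t in tables)
    if den == 0:
        raise ValueError("Mantel-Haenszel denominator is zero")
    return num / den


def forest_table(tables: list[ContingencyTable2x2], level: float = 0.95,
                 min_per_group: int = 10, pool: bool = False):
    """Per-study forest-plot table with the inclusion filter applied.

    Returns (results, exclusions, pooled_or) where results holds one
    StudyResult per included study in input order, exclusions holds the
    excluded studies with reasons, and pooled_or is the Mantel-Haenszel
    estimate when pool=True (the per-study analysis is the primary output;
    pooling is an opt-in extension), else None.
    """
    flags = filter_studies(tables, min_per_group=min_per_group)
    results, exclusions, kept = [], [], []
    for t, f in zip(tables, flags):
        if f.included:
            results.append(study_result(t, level=level))
            kept.append(t)
        else:
            exclusions.append(f)
    pooled = mantel_haenszel_or(kept) if pool and kept else None
    return results, exclusions, pooled
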