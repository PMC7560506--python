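"""Stress-stratified word frequencies and the survey-statistics layer.

Word frequencies count every token occurrence (duplicates within a
report count each time), per stratum or pooled. The survey layer covers
the routine inferential statistics of the study design: Spearman rank
correlations between the ordinal stress-change item and each ordinal
sleep-change item, Pearson chi-square tests of independence (e.g. stress
level × whether a dream was reported), and percentage tables rounded
half-up to one decimal as printed tables conventionally are.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as sps

from oneironet.cooccurrence import UndefinedStatisticError
from oneironet.corpus_io import DreamReport, Stratum, SurveyRecord

__all__ = [
    "SurveyAssociation",
    "ChiSquareResult",
    "word_frequencies",
    "spearman",
    "chi_square",
    "proportion_table",
    "sleep_stress_associations",
    "dream_reporting_by_stress",
]


@dataclass(frozen=True)
class SurveyAssociation:
    """Spearman association of one sleep item with stress change."""

    item: str
    rho: float
    n: int


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def word_frequencies(
    reports: Sequence[DreamReport], stratum: str | Stratum | None = None
) -> list[tuple[str, int]]:
    """Descending (word, token count) list; ties broken alphabetically.

    ``stratum=None`` (or ``"all"``) pools every report, including ones
    with unspecified stratum.
    """
    if stratum is not None and stratum != "all":
        stratum = Stratum(stratum)
        reports = [r for r in reports if r.stratum == stratum]
    counts = Counter(t for r in reports for t in r.tokens)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def chi_square(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("table must be a 2-D non-negative array")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row/column margin")
    res = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(res.statistic), df=int(res.dof),
                           p_value=float(res.pvalue))


def proportion_table(counts: Sequence[int]) -> tuple[float, ...]:
    """Percentage shares of the counts, rounded half-up to one decimal.

    Rounding is per-cell, so the shares sum to 100 only up to rounding
    slack (as in any printed percentage column).
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("counts sum to zero")
    return tuple(
        float((Decimal(100 * c) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP))
        for c in counts
    )


_SLEEP_ITEMS = ("sleep_duration", "sleep_latency", "awakenings",
                "sleep_regularity", "nightmares")


def sleep_stress_associations(records: Sequence[SurveyRecord]) -> list[SurveyAssociation]:
    """Spearman rho of stress change with each worsening-coded sleep item."""
    stress = [r.stress_change for r in records]
    out = []
    for item in _SLEEP_ITEMS:
        values = [getattr(r, item) for r in records]
        out.append(SurveyAssociation(item=item, rho=spearman(stress, values),
                                     n=len(records)))
    return out


def dream_reporting_by_stress(records: Sequence[SurveyRecord]) -> ChiSquareResult:
    """Chi-square of dream reporting (yes/no) across the 4 stress levels."""
    table = np.zeros((4, 2))
    for r in records:
        table[r.stress_change - 1, 0 if r.reported_dream else 1] += 1
    return chi_square(table)
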