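"""Threshold diagnostics, 2x2 reconstruction, odds ratios and chi-square.

Operating characteristics of an integer risk score at a cutoff c use the
strictly-greater rule (call positive when score > c). Published threshold
tables print sensitivity/specificity to 2 d.p. and predictive values to
1 d.p.; :func:`reconstruct_confusion` inverts such a row back to the unique
integer 2x2 table, and :func:`derive_survivor_split` recovers unprinted
survivor cells of a mortality 2x2 by exhaustive integer search against a
printed odds ratio or chi-square statistic.

The odds-ratio confidence interval is Woolf's log-normal interval
exp(ln OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)); the chi-square statistic
is Pearson's, without continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from .roc import GroupedScoreCounts

__all__ = [
    "ConfusionTable",
    "ThresholdMetrics",
    "OddsRatioResult",
    "metrics_at_cutoff",
    "threshold_table",
    "youden_optimal",
    "reconstruct_confusion",
    "odds_ratio_woolf",
    "pearson_chi2",
    "derive_survivor_split",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 classification table (test-positive rows, outcome columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def _pct(num: int, den: int) -> Optional[float]:
    # undefined (0/0) metrics stay missing rather than 0 or 100
    return None if den == 0 else 100.0 * num / den


@dataclass(frozen=True)
class ThresholdMetrics:
    """Sens/spec/PPV/NPV (percent, unrounded) at one strictly-greater cutoff.

    ``None`` marks an undefined metric (empty denominator). ``rounded()``
    applies the conventional reporting precision: sensitivity and
    specificity to 2 d.p., predictive values to 1 d.p.
    """

    cutoff: int
    sens: Optional[float]
    spec: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def rounded(self) -> "ThresholdMetrics":
        r = lambda v, d: None if v is None else round(v, d)
        return ThresholdMetrics(
            self.cutoff, r(self.sens, 2), r(self.spec, 2), r(self.ppv, 1), r(self.npv, 1)
        )

    def youden(self) -> float:
        """Youden index on the percent scale: sens + spec - 100."""
        if self.sens is None or self.spec is None:
            return float("-inf")
        return self.sens + self.spec - 100.0


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Woolf 95% CI plus Pearson chi-square and p-value."""

    odds_ratio: float
    ci95: tuple[float, float]
    chi2: float
    p: float


def confusion_at_cutoff(counts: GroupedScoreCounts, cutoff: int) -> ConfusionTable:
    """2x2 table of the strictly-greater rule at one cutoff."""
    tp = sum(p for s, p, _ in counts.rows if s > cutoff)
    fp = sum(n for s, _, n in counts.rows if s > cutoff)
    return ConfusionTable(tp=tp, fp=fp, fn=counts.n_pos - tp, tn=counts.n_neg - fp)


def metrics_at_cutoff(counts: GroupedScoreCounts, cutoff: int) -> ThresholdMetrics:
    """Operating characteristics of ``score > cutoff`` on grouped counts."""
    t = confusion_at_cutoff(counts, cutoff)
    return ThresholdMetrics(
        cutoff=int(cutoff),
        sens=_pct(t.tp, t.tp + t.fn),
        spec=_pct(t.tn, t.tn + t.fp),
        ppv=_pct(t.tp, t.tp + t.fp),
        npv=_pct(t.tn, t.tn + t.fn),
    )


def threshold_table(counts: GroupedScoreCounts, cutoffs: Sequence[int]) -> list[ThresholdMetrics]:
    """Metrics at each requested cutoff, in the given order."""
    return [metrics_at_cutoff(counts, c) for c in cutoffs]


def youden_optimal(metrics: Sequence[ThresholdMetrics]) -> int:
    """Cutoff maximizing the Youden index; ties go to the smaller cutoff."""
    if not metrics:
        raise ValueError("need at least one metrics row")
    best = max(sorted(metrics, key=lambda m: m.cutoff), key=lambda m: m.youden())
    return best.cutoff


def reconstruct_confusion(sens: float, spec: float, n_pos: int, n_neg: int) -> ConfusionTable:
    """Invert printed sensitivity/specificity (fractions) to an integer 2x2.

    TP and TN are the nearest integers to sens*n_pos and spec*n_neg; FN and
    FP follow by complement. Recomputing sens/spec from the result
    reproduces the inputs at their printed precision.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sens and spec must be fractions in [0, 1]")
    tp = math.floor(sens * n_pos + 0.5)
    tn = math.floor(spec * n_neg + 0.5)
    return ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def _cells(table) -> tuple[int, int, int, int]:
    if isinstance(table, ConfusionTable):
        return table.tp, table.fp, table.fn, table.tn
    a, b, c, d = table
    return int(a), int(b), int(c), int(d)


def pearson_chi2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square of a 2x2 table and its 1-df p-value.

    Accepts a ConfusionTable or any (a, b, c, d) quadruple read row-wise.
    Expected counts come from the margins; no Yates correction is applied.
    """
    a, b, c, d = _cells(table)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2 = float(Fraction(n) * Fraction(a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def odds_ratio_woolf(table) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with Woolf 95% CI, chi-square and p.

    Cells are read row-wise: a = exposed with event, b = exposed without,
    c = unexposed with event, d = unexposed without. All four cells must be
    positive — the Woolf interval has no continuity correction and a zero
    cell makes it undefined.
    """
    a, b, c, d = _cells(table)
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "Woolf interval requires all cells > 0; continuity-corrected "
            "variants are not provided"
        )
    t2 = Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
    or_ = float(t2.oddsratio)
    lo, hi = t2.oddsratio_confint(alpha=0.05)
    chi2, p = pearson_chi2((a, b, c, d))
    return OddsRatioResult(odds_ratio=or_, ci95=(float(lo), float(hi)), chi2=chi2, p=p)


def derive_survivor_split(
    total_n: int,
    deaths_exposed: int,
    deaths_unexposed: int,
    *,
    target_or: Optional[float] = None,
    target_chi2: Optional[float] = None,
    decimals: int = 3,
) -> tuple[int, int]:
    """Recover unprinted survivor cells of a mortality 2x2 by search.

    Given the group total, the two death cells, and one published statistic
    (odds ratio or Pearson chi-square, printed to ``decimals``), enumerate
    every integer split of the ``total_n - deaths`` survivors between the
    exposed and unexposed groups and return the unique ``(survivors_exposed,
    survivors_unexposed)`` whose statistic rounds to the target. Raises if
    no split or more than one split matches.
    """
    if (target_or is None) == (target_chi2 is None):
        raise ValueError("provide exactly one of target_or / target_chi2")
    deaths = deaths_exposed + deaths_unexposed
    if deaths >= total_n:
        raise ValueError("deaths meet or exceed the group total")
    survivors = total_n - deaths
    matches = []
    for s_exp in range(survivors + 1):
        s_un = survivors - s_exp
        cells = (deaths_exposed, s_exp, deaths_unexposed, s_un)
        try:
            if target_or is not None:
                value = _cells(cells)[0] * s_un / (s_exp * deaths_unexposed)
                target = target_or
            else:
                value, _ = pearson_chi2(cells)
                target = target_chi2
        except (ZeroDivisionError, ValueError):
            continue
        if round(value, decimals) == round(target, decimals):
            matches.append((s_exp, s_un))
    if not matches:
        raise ValueError("no integer survivor split matches the target statistic")
    if len(matches) > 1:
        raise ValueError(f"ambiguous: {len(matches)} survivor splits match the target")
    return matches[0]
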