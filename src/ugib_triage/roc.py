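"""Empirical ROC curves, tie-corrected AUC, and the DeLong method.

Ordinal risk scores produce heavily tied data, so the cohort's native shape
is a grouped table: one row per distinct score with counts of
outcome-positive and outcome-negative patients (:class:`GroupedScoreCounts`).
The AUC is the tie-corrected Mann-Whitney probability

    AUC = [ #(score_pos > score_neg) + 0.5 * #ties ] / (n_pos * n_neg),

computed in exact rational arithmetic for integer counts and identical to
the trapezoidal area under the empirical ROC curve. Standard errors,
confidence intervals and paired comparisons of correlated AUCs use the
nonparametric structural-components estimator of DeLong, DeLong and
Clarke-Pearson: per-patient placement values whose sample (co)variances
give the variance of the AUC and of a difference of two AUCs measured on
the same patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupedScoreCounts",
    "RocCurve",
    "AucEstimate",
    "DeLongComparison",
    "roc_points",
    "auc_tied",
    "delong_se",
    "delong_paired_test",
]


@dataclass(frozen=True)
class GroupedScoreCounts:
    """Per-score outcome counts: rows of ``(score, n_pos, n_neg)``.

    Scores must be strictly increasing and counts non-negative. This is the
    grouped form in which a scored cohort is tabulated against a binary
    outcome.
    """

    rows: tuple[tuple[int, int, int], ...]

    def __init__(self, rows: Iterable[Sequence[int]]):
        rows = tuple((int(s), int(p), int(n)) for s, p, n in rows)
        scores = [s for s, _, _ in rows]
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be strictly increasing")
        if any(p < 0 or n < 0 for _, p, n in rows):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "rows", rows)

    @property
    def n_pos(self) -> int:
        return sum(p for _, p, _ in self.rows)

    @property
    def n_neg(self) -> int:
        return sum(n for _, _, n in self.rows)

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(s for s, _, _ in self.rows)

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Ungroup to aligned per-patient ``(scores, labels)`` arrays."""
        scores, labels = [], []
        for s, p, n in self.rows:
            scores.extend([s] * (p + n))
            labels.extend([1] * p + [0] * n)
        return np.asarray(scores, dtype=float), np.asarray(labels, dtype=int)

    @classmethod
    def from_labelled(cls, scores, labels) -> "GroupedScoreCounts":
        """Group aligned per-patient integer scores and 0/1 labels."""
        scores = np.asarray(scores)
        labels = np.asarray(labels, dtype=int)
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must be aligned")
        rows = []
        for s in np.unique(scores):
            mask = scores == s
            rows.append((int(s), int(labels[mask].sum()), int((~labels.astype(bool))[mask].sum())))
        return cls(rows)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("score,n_pos,n_neg\n")
            for s, p, n in self.rows:
                fh.write(f"{s},{p},{n}\n")

    @classmethod
    def from_csv(cls, path) -> "GroupedScoreCounts":
        import pandas as pd

        frame = pd.read_csv(path, comment="#")
        return cls(frame[["score", "n_pos", "n_neg"]].itertuples(index=False))


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC polygon: ``(fpr, tpr)`` points including (0,0), (1,1)."""

    points: tuple[tuple[float, float], ...]

    def trapezoidal_area(self) -> float:
        fpr = np.array([p[0] for p in self.points])
        tpr = np.array([p[1] for p in self.points])
        return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class AucEstimate:
    """AUC with DeLong standard error and normal 95% CI (clipped to [0,1])."""

    auc: float
    se: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two correlated AUCs on the same patients."""

    auc_a: float
    auc_b: float
    z: float
    p: float


def _check_classes(n_pos: int, n_neg: int) -> None:
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"need at least one positive and one negative (got {n_pos} / {n_neg})"
        )


def roc_points(counts: GroupedScoreCounts) -> RocCurve:
    """Empirical ROC of a grouped score table.

    Each distinct score, taken in descending order, serves as a cutoff c
    under the strictly-greater rule (positive call when score > c):
    TPR(c) = #(pos with score > c) / n_pos and likewise FPR on negatives.
    The (0,0) and (1,1) endpoints are always included.
    """
    n_pos, n_neg = counts.n_pos, counts.n_neg
    _check_classes(n_pos, n_neg)
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for s, p, n in reversed(counts.rows):
        tp += p
        fp += n
        pts.append((fp / n_neg, tp / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    # dedupe consecutive identical points (zero-count rows)
    out = [pts[0]]
    for pt in pts[1:]:
        if pt != out[-1]:
            out.append(pt)
    return RocCurve(tuple(out))


def auc_tied(counts: GroupedScoreCounts) -> float:
    """Tie-corrected Mann-Whitney AUC of a grouped score table.

    Exact rational arithmetic over all n_pos * n_neg positive-negative
    pairs: a strictly higher positive score counts 1, a tie counts 1/2.
    Equal to the trapezoid area under :func:`roc_points`.
    """
    n_pos, n_neg = counts.n_pos, counts.n_neg
    _check_classes(n_pos, n_neg)
    twice_wins = 0  # 2*concordant + ties, in integers
    neg_below = 0
    for s, p, n in counts.rows:
        twice_wins += p * (2 * neg_below + n)
        neg_below += n
    return float(Fraction(twice_wins, 2 * n_pos * n_neg))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # fraction of negatives each positive beats (ties half), and vice versa
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = (pos.size - hi + 0.5 * (hi - lo)) / pos.size
    return v10, v01


def _component_var(v: np.ndarray) -> float:
    # sample variance of structural components; a single component carries
    # no estimable variability and contributes 0
    return float(np.var(v, ddof=1)) if v.size > 1 else 0.0


def _component_cov(u: np.ndarray, v: np.ndarray) -> float:
    if u.size > 1:
        return float(np.cov(u, v, ddof=1)[0, 1])
    return 0.0


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def delong_se(scores, labels) -> AucEstimate:
    """AUC with DeLong variance from per-patient scores and 0/1 labels.

    The variance is S10/m + S01/n where S10, S01 are the sample variances
    of the positive- and negative-side placement values and m, n the class
    sizes; the 95% CI is auc +/- 1.96*se, truncated to [0, 1].
    """
    scores, labels = _as_arrays(scores, labels)
    m = int(labels.sum())
    n = int(labels.size - m)
    _check_classes(m, n)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = _component_var(v10) / m + _component_var(v01) / n
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return AucEstimate(auc=auc, se=se, ci95=ci)


def delong_paired_test(scores_a, scores_b, labels) -> DeLongComparison:
    """Two-sided DeLong test for equality of two correlated AUCs.

    Both score lists must be aligned to the same patients and labels;
    z = (auc_a - auc_b) / sqrt(var_a + var_b - 2*cov_ab) with variances and
    covariance from the placement components, p from the standard normal.
    Identical AUC estimates give z = 0, p = 1.
    """
    scores_a, labels = _as_arrays(scores_a, labels)
    scores_b, _ = _as_arrays(scores_b, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score lists must have equal length")
    m = int(labels.sum())
    n = int(labels.size - m)
    _check_classes(m, n)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a = float(va10.mean())
    auc_b = float(vb10.mean())
    var = (
        _component_var(va10) / m
        + _component_var(va01) / n
        + _component_var(vb10) / m
        + _component_var(vb01) / n
        - 2 * (_component_cov(va10, vb10) / m + _component_cov(va01, vb01) / n)
    )
    if auc_a == auc_b:
        z = 0.0
    elif var <= 0:
        z = float(np.inf) if auc_a > auc_b else float(-np.inf)
    else:
        z = float((auc_a - auc_b) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z))) if z != 0 else 1.0
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, z=z, p=min(p, 1.0))
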