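"""GBS, modified GBS and pre-endoscopy Rockall score calculators.

All three scores are additive integer point systems over presentation
variables, applicable before endoscopy:

* mGBS (0-16): the four quantitative Blatchford items — pulse, systolic
  blood pressure, blood urea nitrogen, haemoglobin (sex-specific bands).
* GBS (0-23): mGBS plus four presence flags — hepatic disease (2), cardiac
  failure (2), melena (1), syncope (2).
* Pre-endoscopy Rockall (0-7): age band + shock (hypotension 2 points,
  else tachycardia 1) + comorbidity level (major 2, severe 3).

Band edges follow the printed one-decimal band labels read as half-open
intervals (e.g. BUN "22.4-27.9" means [22.4, 28)), so every physiologic
value falls in exactly one band. Note the deliberate asymmetry in the pulse
thresholds: mGBS scores pulse >= 100, the Rockall shock item pulse > 100.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .records import PatientRecord, ValidationError
from .roc import GroupedScoreCounts

__all__ = [
    "compute_mgbs",
    "compute_gbs",
    "compute_pre_e_rs",
    "score_cohort",
    "score_frame",
    "mgbs_scores",
    "gbs_scores",
    "pre_e_rs_scores",
    "SCORE_NAMES",
    "OUTCOME_NAMES",
]

SCORE_NAMES = ("gbs", "mgbs", "pre_e_rs")
OUTCOME_NAMES = ("intervention", "death30")

_COMORBIDITY_POINTS = {"none": 0, "major": 2, "severe": 3}


def _pulse_points(pulse: float) -> int:
    return 1 if pulse >= 100 else 0


def _sbp_points(sbp: float) -> int:
    if sbp < 90:
        return 3
    if sbp < 100:
        return 2
    if sbp < 110:
        return 1
    return 0


def _bun_points(bun: float) -> int:
    if bun >= 70:
        return 6
    if bun >= 28:
        return 4
    if bun >= 22.4:
        return 3
    if bun >= 19:
        return 2
    return 0


def _hb_points(hb: float, sex: str) -> int:
    if hb < 10:
        return 6
    if sex == "male":
        if hb < 12:
            return 3
        if hb < 13:
            return 1
        return 0
    return 1 if hb < 12 else 0


def compute_mgbs(record: PatientRecord) -> int:
    """Modified Glasgow-Blatchford score (0-16) of one patient.

    Sum of the pulse, systolic-BP, BUN and haemoglobin band points; the
    subjective flag items of the full GBS are excluded.
    """
    return (
        _pulse_points(record.pulse)
        + _sbp_points(record.sbp)
        + _bun_points(record.bun)
        + _hb_points(record.hb, record.sex)
    )


def compute_gbs(record: PatientRecord) -> int:
    """Glasgow-Blatchford score (0-23): mGBS plus the four presence flags."""
    return (
        compute_mgbs(record)
        + 2 * record.hepatic_disease
        + 2 * record.cardiac_failure
        + 1 * record.melena
        + 2 * record.syncope
    )


def compute_pre_e_rs(record: PatientRecord) -> int:
    """Pre-endoscopy Rockall score (0-7) of one patient.

    Age (<60: 0, 60-79: 1, >=80: 2) + shock + comorbidity. Shock is a
    single ordinal item: hypotension (SBP < 100) scores 2 and takes
    precedence over tachycardia (pulse > 100, 1 point); the two are never
    summed.
    """
    if record.age >= 80:
        points = 2
    elif record.age >= 60:
        points = 1
    else:
        points = 0
    if record.sbp < 100:
        points += 2
    elif record.pulse > 100:
        points += 1
    points += _COMORBIDITY_POINTS[record.rockall_comorbidity]
    return points


# ---------------------------------------------------------------------------
# vectorized forms over the cohort CSV schema


def _require(frame: pd.DataFrame, columns: Sequence[str]) -> None:
    for col in columns:
        if col not in frame.columns:
            raise ValidationError(f"missing mandatory column {col!r}")
        if col in ("pulse", "sbp", "bun_mg_dl", "hb_g_dl"):
            vals = pd.to_numeric(frame[col], errors="coerce")
            bad = ~(vals > 0)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {i}: {col} must be strictly positive, got {frame[col].iloc[i]!r}"
                )


def mgbs_scores(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized mGBS over a cohort table (CSV schema columns)."""
    _require(frame, ["pulse", "sbp", "bun_mg_dl", "hb_g_dl", "sex"])
    pulse = frame["pulse"].to_numpy(float)
    sbp = frame["sbp"].to_numpy(float)
    bun = frame["bun_mg_dl"].to_numpy(float)
    hb = frame["hb_g_dl"].to_numpy(float)
    male = frame["sex"].to_numpy() == "male"

    pts = (pulse >= 100).astype(int)
    pts += np.select([sbp < 90, sbp < 100, sbp < 110], [3, 2, 1], default=0)
    pts += np.select([bun >= 70, bun >= 28, bun >= 22.4, bun >= 19], [6, 4, 3, 2], default=0)
    hb_male = np.select([hb < 10, hb < 12, hb < 13], [6, 3, 1], default=0)
    hb_female = np.select([hb < 10, hb < 12], [6, 1], default=0)
    pts += np.where(male, hb_male, hb_female)
    return pts


def _flag_array(frame: pd.DataFrame, name: str) -> np.ndarray:
    if name not in frame.columns:
        return np.zeros(len(frame), dtype=int)
    return frame[name].fillna(0).astype(int).to_numpy()


def gbs_scores(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized GBS; absent flag columns count as flag-absent."""
    return (
        mgbs_scores(frame)
        + 2 * _flag_array(frame, "hepatic_disease")
        + 2 * _flag_array(frame, "cardiac_failure")
        + 1 * _flag_array(frame, "melena")
        + 2 * _flag_array(frame, "syncope")
    )


def pre_e_rs_scores(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized pre-endoscopy Rockall score over a cohort table."""
    _require(frame, ["age", "pulse", "sbp", "rockall_comorbidity"])
    age = frame["age"].to_numpy(float)
    pulse = frame["pulse"].to_numpy(float)
    sbp = frame["sbp"].to_numpy(float)
    comorbidity = frame["rockall_comorbidity"].fillna("none")
    unknown = ~comorbidity.isin(_COMORBIDITY_POINTS)
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValidationError(
            f"row {i}: rockall_comorbidity must be none|major|severe, "
            f"got {comorbidity.iloc[i]!r}"
        )
    pts = np.select([age >= 80, age >= 60], [2, 1], default=0)
    pts += np.select([sbp < 100, pulse > 100], [2, 1], default=0)
    pts += comorbidity.map(_COMORBIDITY_POINTS).to_numpy(int)
    return pts


_VECTORIZED = {"gbs": gbs_scores, "mgbs": mgbs_scores, "pre_e_rs": pre_e_rs_scores}
_SCALAR = {"gbs": compute_gbs, "mgbs": compute_mgbs, "pre_e_rs": compute_pre_e_rs}


def score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort table with gbs/mgbs/pre_e_rs columns."""
    out = frame.copy()
    for name in SCORE_NAMES:
        out[name] = _VECTORIZED[name](frame)
    return out


Cohort = Union[pd.DataFrame, Iterable[PatientRecord]]


def score_cohort(records: Cohort, score_name: str, outcome_name: str) -> GroupedScoreCounts:
    """Tabulate a cohort into per-score outcome counts.

    Every record must carry the named outcome flag; the result has one row
    per distinct score value with counts of outcome-positive and
    outcome-negative patients, conserving the cohort size.
    """
    if score_name not in SCORE_NAMES:
        raise ValueError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")
    if outcome_name not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome {outcome_name!r}; expected one of {OUTCOME_NAMES}")
    if isinstance(records, pd.DataFrame):
        frame = records
        if outcome_name not in frame.columns or frame[outcome_name].isna().any():
            raise ValidationError(f"every record must carry the {outcome_name!r} outcome")
        scores = _VECTORIZED[score_name](frame)
        labels = frame[outcome_name].astype(int).to_numpy()
    else:
        records = list(records)
        outcomes = [getattr(r, outcome_name) for r in records]
        if any(o is None for o in outcomes):
            raise ValidationError(f"every record must carry the {outcome_name!r} outcome")
        scores = np.array([_SCALAR[score_name](r) for r in records], dtype=int)
        labels = np.array([int(o) for o in outcomes], dtype=int)
    if scores.size == 0:
        return GroupedScoreCounts([])
    return GroupedScoreCounts.from_labelled(scores, labels)
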