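"""Patient records for pre-endoscopy risk scoring in upper-GI bleeding.

A cohort is a flat table, one row per emergency-department presentation,
with the demographic, vital-sign, laboratory, symptom and comorbidity
variables consumed by the Glasgow-Blatchford score (GBS), the modified GBS
(mGBS) and the pre-endoscopy Rockall score, plus the two study outcomes
(need of intervention, 30-day death). :class:`PatientRecord` is the
single-subject view; :func:`read_cohort_csv` / :func:`write_cohort_csv`
handle the fixed CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "ValidationError",
    "CSV_COLUMNS",
    "COMORBIDITY_LEVELS",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "validate_frame",
]

#: Fixed column order of the cohort CSV schema.
CSV_COLUMNS = [
    "age",
    "sex",
    "pulse",
    "sbp",
    "bun_mg_dl",
    "hb_g_dl",
    "melena",
    "syncope",
    "hepatic_disease",
    "cardiac_failure",
    "rockall_comorbidity",
    "endoscopy_delay_h",
    "intervention",
    "death30",
]

#: Rockall comorbidity levels: none; major (IHD/CHF/other major organ
#: failure); severe (renal failure, hepatic failure or disseminated
#: malignancy).
COMORBIDITY_LEVELS = ("none", "major", "severe")

_FLAGS = ("melena", "syncope", "hepatic_disease", "cardiac_failure")
_OPTIONAL_FLAGS = ("intervention", "death30")


class ValidationError(ValueError):
    """A record or table violates the patient schema; names the field."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject's clinical variables and outcomes.

    Vitals and labs are mandatory and strictly positive; flags default to
    absent (the scores award points only for *presence*); outcomes and the
    door-to-endoscopy delay are optional because not every analysis needs
    them.

    Parameters
    ----------
    age : int
        Age in years; adults only (>= 18).
    sex : str
        ``"male"`` or ``"female"`` (the Blatchford haemoglobin bands are
        sex-specific).
    pulse : float
        Heart rate, beats/min.
    sbp : float
        Systolic blood pressure, mmHg.
    bun : float
        Blood urea nitrogen, mg/dL.
    hb : float
        Haemoglobin, g/dL.
    melena, syncope, hepatic_disease, cardiac_failure : bool
        Presence flags scored by the GBS.
    rockall_comorbidity : str
        ``"none"``, ``"major"`` or ``"severe"`` (Rockall comorbidity item).
    endoscopy_delay_h : float, optional
        Hours from presentation to endoscopy.
    intervention : bool, optional
        Transfusion or endoscopic/radiologic/surgical haemostasis.
    death30 : bool, optional
        Death within 30 days of presentation.
    """

    age: int
    sex: str
    pulse: float
    sbp: float
    bun: float
    hb: float
    melena: bool = False
    syncope: bool = False
    hepatic_disease: bool = False
    cardiac_failure: bool = False
    rockall_comorbidity: str = "none"
    endoscopy_delay_h: Optional[float] = None
    intervention: Optional[bool] = None
    death30: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.age >= 18:
            raise ValidationError(f"age must be >= 18, got {self.age!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("pulse", "sbp", "bun", "hb"):
            value = getattr(self, name)
            if value is None or not value > 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.rockall_comorbidity not in COMORBIDITY_LEVELS:
            raise ValidationError(
                "rockall_comorbidity must be one of "
                f"{COMORBIDITY_LEVELS}, got {self.rockall_comorbidity!r}"
            )


def _as_flag(value, column: str, row: int) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if value in (0, 1, True, False, "0", "1"):
        return bool(int(value))
    raise ValidationError(f"row {row}: {column} must be 0/1, got {value!r}")


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Convert a schema-conformant DataFrame to :class:`PatientRecord` list.

    Flag columns may be absent entirely (treated as all-false); the
    optional columns may hold missing values.
    """
    records = []
    for i, row in enumerate(frame.to_dict("records")):
        kwargs = dict(
            age=int(row["age"]),
            sex=str(row["sex"]),
            pulse=float(row["pulse"]),
            sbp=float(row["sbp"]),
            bun=float(row["bun_mg_dl"]),
            hb=float(row["hb_g_dl"]),
            rockall_comorbidity=str(row.get("rockall_comorbidity", "none")),
        )
        for flag in _FLAGS:
            kwargs[flag] = bool(_as_flag(row.get(flag, 0), flag, i) or False)
        for flag in _OPTIONAL_FLAGS:
            kwargs[flag] = _as_flag(row.get(flag), flag, i)
        delay = row.get("endoscopy_delay_h")
        if delay is not None and not pd.isna(delay):
            kwargs["endoscopy_delay_h"] = float(delay)
        try:
            records.append(PatientRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records into the fixed CSV schema (one row per patient)."""
    rows = []
    for r in records:
        rows.append(
            {
                "age": r.age,
                "sex": r.sex,
                "pulse": r.pulse,
                "sbp": r.sbp,
                "bun_mg_dl": r.bun,
                "hb_g_dl": r.hb,
                "melena": int(r.melena),
                "syncope": int(r.syncope),
                "hepatic_disease": int(r.hepatic_disease),
                "cardiac_failure": int(r.cardiac_failure),
                "rockall_comorbidity": r.rockall_comorbidity,
                "endoscopy_delay_h": r.endoscopy_delay_h,
                "intervention": None if r.intervention is None else int(r.intervention),
                "death30": None if r.death30 is None else int(r.death30),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def validate_frame(frame: pd.DataFrame) -> None:
    """Validate a cohort table against the schema, field by field.

    Raises :class:`ValidationError` naming the first offending row and
    column. Mandatory columns: age, sex, pulse, sbp, bun_mg_dl, hb_g_dl,
    rockall_comorbidity.
    """
    mandatory = ["age", "sex", "pulse", "sbp", "bun_mg_dl", "hb_g_dl"]
    for col in mandatory:
        if col not in frame.columns:
            raise ValidationError(f"missing mandatory column {col!r}")
    frame_to_records(frame)  # per-row checks with row diagnostics


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns the validated DataFrame."""
    frame = pd.read_csv(path)
    validate_frame(frame)
    return frame


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a cohort table in the fixed schema (flags as 0/1 integers)."""
    out = frame.copy()
    cols = [c for c in CSV_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in CSV_COLUMNS]
    out[cols + extra].to_csv(path, index=False)
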