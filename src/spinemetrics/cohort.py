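"""Subject classification, stratification and exclusion rules.

Turns measured parameter panels into the tabular substrate of the
population analyses: one row per kept subject with demographics, the full
parameter panel, the age stratum and the deformity/scoliosis flags.

Thresholds are strict inequalities: a subject is scoliotic when the maximal
coronal Cobb angle exceeds 10 degrees, and deformed when that holds and/or
the sagittal vertical axis exceeds 5 cm (signed, i.e. anterior imbalance);
boundary subjects at exactly 10 deg / 5 cm are classified as non-deformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .geometry import SpineParameters, compute_all
from .landmarks import SpineReconstruction

__all__ = [
    "AGE_GROUP_LABELS",
    "COBB_THRESHOLD_DEG",
    "SVA_THRESHOLD_CM",
    "SubjectRecord",
    "age_group",
    "classify",
    "apply_exclusions",
    "build_cohort",
    "cohort_dataframe",
]

logger = logging.getLogger(__name__)

AGE_GROUP_LABELS = ("10-18", "19-44", "45-64", "65-79", "80+")
COBB_THRESHOLD_DEG = 10.0
SVA_THRESHOLD_CM = 5.0

#: caller-supplied exclusion flags (visual-inspection criteria upstream of
#: any landmark-level information)
EXCLUSION_FLAGS = ("implants", "prior_surgery", "neuromuscular_congenital")


def age_group(age: float) -> str:
    """The age stratum containing ``age`` (integer-year bounds inclusive).

    Ages below 10 are outside the study population and raise; exclusion
    handling belongs to :func:`apply_exclusions`.
    """
    if age < 0 or not math.isfinite(age):
        raise ValueError(f"invalid age {age}")
    if age < 10:
        raise ValueError(f"age {age} below the 10-year study minimum")
    yrs = math.floor(age)
    if yrs <= 18:
        return "10-18"
    if yrs <= 44:
        return "19-44"
    if yrs <= 64:
        return "45-64"
    if yrs <= 79:
        return "65-79"
    return "80+"


@dataclass
class SubjectRecord:
    """One analyzed subject: demographics + parameters + derived strata."""

    subject_id: str
    age: float
    sex: str
    params: SpineParameters
    age_group: str
    deformity: bool
    scoliosis: bool
    excluded: bool = False
    exclusion_reason: str = ""

    def as_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "age": self.age,
            "sex": self.sex,
            "age_group": self.age_group,
        }
        d.update(self.params.as_dict())
        d.update(
            deformity=self.deformity,
            scoliosis=self.scoliosis,
            excluded=self.excluded,
            exclusion_reason=self.exclusion_reason,
        )
        return d


def classify(params: SpineParameters, age: float, sex: str,
             subject_id: str = "") -> SubjectRecord:
    """Derive the stratum and deformity flags for one parameter panel."""
    scoliosis = params.cobb_angle > COBB_THRESHOLD_DEG
    deformity = scoliosis or params.sva > SVA_THRESHOLD_CM
    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        params=params,
        age_group=age_group(age),
        deformity=deformity,
        scoliosis=scoliosis,
    )


def apply_exclusions(
    records: Sequence[SubjectRecord],
    flags: Mapping[str, Mapping[str, bool]] | None = None,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split records into (kept, excluded-with-reasons).

    ``flags`` maps subject_id → {flag: bool} for the visual-inspection
    exclusion criteria (implants, prior surgery, neuromuscular/congenital
    deformity); subjects younger than 10 are excluded regardless.
    """
    flags = flags or {}
    kept, excluded = [], []
    for rec in records:
        reasons = []
        if rec.age < 10:
            reasons.append("age<10")
        for flag, value in (flags.get(rec.subject_id) or {}).items():
            if flag not in EXCLUSION_FLAGS:
                raise ValueError(f"unknown exclusion flag {flag!r}")
            if value:
                reasons.append(flag)
        if reasons:
            rec.excluded = True
            rec.exclusion_reason = ";".join(reasons)
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def build_cohort(
    spines: Sequence[SpineReconstruction],
    flags: Mapping[str, Mapping[str, bool]] | None = None,
    sva_reference: str = "T1",
) -> pd.DataFrame:
    """measure → classify → exclude; returns the kept cohort as a DataFrame.

    Geometry failures are logged per subject without aborting the batch.
    Subjects younger than 10 are routed through :func:`apply_exclusions`
    rather than rejected by :func:`age_group`.
    """
    records, failures = [], 0
    for s in spines:
        try:
            params = compute_all(s, sva_reference=sva_reference)
            grp_age = max(s.age, 10.0)  # under-10s are excluded downstream
            rec = classify(params, grp_age, s.sex, subject_id=s.subject_id)
            rec.age = s.age
            records.append(rec)
        except Exception:
            failures += 1
            logger.exception("measurement failed for subject %s", s.subject_id)
    kept, excluded = apply_exclusions(records, flags)
    logger.info(
        "cohort: %d measured, %d failed, %d kept, %d excluded",
        len(records), failures, len(kept), len(excluded),
    )
    return cohort_dataframe(kept)


def cohort_dataframe(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Records as a DataFrame with unique subject ids."""
    df = pd.DataFrame([r.as_dict() for r in records])
    if len(df) and df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes[:5]}")
    return df
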