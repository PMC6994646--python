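"""Participant-level exclusion rules and cohort assembly.

Children enter the analysis cohort only if they have the behavioral measure
under study, a credible questionnaire protocol (BRIEF inconsistency score
<= 7), acceptable head motion (<= 4 mm maximum absolute displacement), and
a score within 3 SD of the sample mean on the measure being modelled.  The
outlier rule is applied per measure, so a child can be excluded from the
inhibition analysis yet retained for shifting and emotional control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: behavioral-regulation measures -> phenotype column (canonical names)
MEASURE_COLUMNS = {
    "inhibit": "brief_inhibit_t",
    "shift": "brief_shift_t",
    "emocontrol": "brief_emocontrol_t",
}

INCONSISTENCY_MAX = 7.0   # raw BRIEF inconsistency; exclusion is strict >
MOTION_MAX_MM = 4.0       # maximum absolute displacement; exclusion is strict >
OUTLIER_SD = 3.0          # behavioral outlier rule; exclusion is strict >


@dataclass
class ParticipantRecord:
    """One child's phenotype row.  ``None`` marks a missing field."""

    participant_id: str
    site: Optional[str] = None
    group: Optional[str] = None            # "TD" or "ASD"
    age: Optional[float] = None
    sex: Optional[str] = None              # "M" / "F"
    handedness: Optional[str] = None       # "L" / "A" / "R"
    motion_mm: Optional[float] = None      # max abs displacement, pre-cleaning
    motion_mm_after: Optional[float] = None
    fiq: Optional[float] = None
    viq: Optional[float] = None
    piq: Optional[float] = None
    srs_total_t: Optional[float] = None
    brief_inhibit_t: Optional[float] = None
    brief_shift_t: Optional[float] = None
    brief_emocontrol_t: Optional[float] = None
    brief_inconsistency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.motion_mm is not None and self.motion_mm < 0:
            raise ValueError(
                f"motion_mm must be >= 0, got {self.motion_mm} "
                f"for {self.participant_id!r}"
            )


@dataclass
class CohortFilterReport:
    """Outcome of the exclusion rules: retained ids plus one reason per exclusion."""

    retained_ids: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    measure: str = ""

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def flag_behavioral_outliers(scores: Sequence[float], k: float = OUTLIER_SD) -> set[int]:
    """Indices of scores further than ``k`` sample SDs from the mean.

    Mean and SD (n-1 denominator) are computed once over all non-missing
    scores, candidate included (single pass, no iteration).  If the SD is
    zero nothing can exceed it and no index is flagged.  The threshold is
    strict: a deviation of exactly k SD is retained.
    """
    arr = np.array([np.nan if _is_missing(s) else float(s) for s in scores])
    ok = np.isfinite(arr)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing scores to define outliers")
    mean = arr[ok].mean()
    sd = arr[ok].std(ddof=1)
    if sd == 0:
        return set()
    flagged = np.abs(arr - mean) > k * sd
    return set(np.flatnonzero(flagged & ok).tolist())


def apply_exclusion_criteria(
    records: Sequence[ParticipantRecord], measure: str
) -> CohortFilterReport:
    """Apply the exclusion rules, in order, for one behavioral measure.

    Rule order (each participant gets the first reason that fires):

    1. missing behavior score for ``measure``
    2. BRIEF inconsistency > 7
    3. motion > 4 mm maximum absolute displacement
    4. behavioral outlier (> 3 SD from the mean of the remaining sample,
       on the chosen measure)

    The outlier statistics are computed on the sample that survives rules
    1-3, i.e. the sample the model would otherwise be built on.
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError(
            f"unknown measure {measure!r}; expected one of {sorted(MEASURE_COLUMNS)}"
        )
    col = MEASURE_COLUMNS[measure]

    excluded: dict[str, str] = {}
    survivors: list[ParticipantRecord] = []
    for rec in records:
        score = getattr(rec, col)
        if _is_missing(score):
            excluded[rec.participant_id] = "missing_behavior"
        elif not _is_missing(rec.brief_inconsistency) and rec.brief_inconsistency > INCONSISTENCY_MAX:
            excluded[rec.participant_id] = "inconsistency"
        elif not _is_missing(rec.motion_mm) and rec.motion_mm > MOTION_MAX_MM:
            excluded[rec.participant_id] = "motion"
        else:
            survivors.append(rec)

    if len(survivors) >= 2:
        scores = [getattr(rec, col) for rec in survivors]
        flagged = flag_behavioral_outliers(scores, k=OUTLIER_SD)
        for idx in sorted(flagged):
            excluded[survivors[idx].participant_id] = f"behavioral_outlier:{measure}"
        survivors = [rec for i, rec in enumerate(survivors) if i not in flagged]

    return CohortFilterReport(
        retained_ids=[rec.participant_id for rec in survivors],
        excluded=excluded,
        measure=measure,
    )


_RECORD_FIELDS = [f.name for f in fields(ParticipantRecord)]


def records_from_phenotype(phenotype: pd.DataFrame) -> list[ParticipantRecord]:
    """Build records from a phenotype table with canonical column names."""
    df = phenotype.reset_index() if phenotype.index.name == "participant_id" else phenotype
    recs = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _RECORD_FIELDS:
            if name in row.index:
                val = row[name]
                if isinstance(val, float) and math.isnan(val):
                    val = None
                kwargs[name] = val
        kwargs["participant_id"] = str(row["participant_id"])
        recs.append(ParticipantRecord(**kwargs))
    return recs


def filter_phenotype(phenotype: pd.DataFrame, measure: str) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply exclusion rules to a phenotype table; return retained rows + report."""
    records = records_from_phenotype(phenotype)
    report = apply_exclusion_criteria(records, measure)
    key = phenotype["participant_id"].astype(str) if "participant_id" in phenotype.columns else phenotype.index.astype(str)
    keep = key.isin(report.retained_ids)
    return phenotype.loc[np.asarray(keep)], report
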