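"""Patient records and threshold-based severity classification.

Five classification criteria stratify an HAE cohort:

* **CC1** — age at disease onset (years).  Early onset (around or before
  puberty) marks a severe lifelong course, late onset a mild one.
* **CC2** — average number of attacks per year over the last 5 years.
* **CC3** — all-time maximum number of attacks in a single year.
* **CC4** — number of attacks in the year before blood collection; this is
  the short-term criterion used for the transcriptomic contrasts and, unlike
  CC1..CC3, has no intermediate gap.
* **CC5** — long-term prophylaxis status, defined only for the CC4 cohort.

CC1..CC3 deliberately leave a gap between the severe and mild cut-offs so
that patients with borderline values are assigned to neither side
(``intermediate``) and excluded from severe-vs-mild contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

SEVERE = "S"
MILD = "M"
INTERMEDIATE = "intermediate"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class PatientRecord:
    """Clinical attributes of one subject.

    ``onset_age_years is None`` encodes an asymptomatic mutation carrier.
    Controls carry ``role='control'`` and no attack data.
    """

    patient_id: str
    role: str = "patient"  # 'patient' | 'control'
    onset_age_years: Optional[int] = None
    attacks_avg_5y: Optional[float] = None
    attacks_max_year: Optional[float] = None
    attacks_last_year: Optional[float] = None
    ltp: bool = False
    serping1_class: str = "none"  # 'nmd' | 'non_nmd' | 'none'
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ("patient", "control"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.serping1_class not in ("nmd", "non_nmd", "none"):
            raise ValueError(f"unknown serping1_class {self.serping1_class!r}")
        for name in ("attacks_avg_5y", "attacks_max_year", "attacks_last_year"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.onset_age_years is not None and self.onset_age_years < 0:
            raise ValueError("onset_age_years must be non-negative")
        if self.role == "control" and any(
            getattr(self, n) is not None
            for n in ("attacks_avg_5y", "attacks_max_year", "attacks_last_year")
        ):
            raise ValueError("controls must not carry attack data")


@dataclass(frozen=True)
class SeverityThresholds:
    """Classification cut-offs; defaults reproduce the study constants.

    The mild bounds are exclusive in the direction stated below:
    onset > ``cc1_mild_above`` years is mild, < ``cc2_mild_below``
    average attacks/year is mild, etc.
    """

    cc1_severe_max: int = 11     # onset <= 11 y -> severe
    cc1_mild_above: int = 15     # onset  > 15 y -> mild (min observed mild value 16)
    cc2_severe_min: float = 6.0  # avg   >= 6 /y -> severe
    cc2_mild_below: float = 3.0  # avg    < 3 /y -> mild
    cc3_severe_above: float = 13.0  # max  > 13 /y -> severe
    cc3_mild_below: float = 6.0     # max   < 6 /y -> mild
    cc4_severe_min: float = 5.0     # last year >= 5 -> severe, else mild

    asymptomatic_is_mild: bool = True


@dataclass(frozen=True)
class SeverityAssignment:
    patient_id: str
    cc1: str
    cc2: str
    cc3: str
    cc4: str
    cc5: str  # 'Y' | 'N' | 'not_applicable'
    asymptomatic: bool = False


def classify_patient(
    record: PatientRecord, thresholds: SeverityThresholds | None = None
) -> SeverityAssignment:
    """Assign one patient to the five severity criteria.

    Raises ``ValueError`` for control records: controls are a comparison
    group, not members of any CC subgroup.
    """
    t = thresholds or SeverityThresholds()
    if record.role != "patient":
        raise ValueError("classify_patient expects a patient record, not a control")

    asymptomatic = record.onset_age_years is None
    if asymptomatic:
        cc1 = MILD if t.asymptomatic_is_mild else INTERMEDIATE
    elif record.onset_age_years <= t.cc1_severe_max:
        cc1 = SEVERE
    elif record.onset_age_years > t.cc1_mild_above:
        cc1 = MILD
    else:
        cc1 = INTERMEDIATE

    avg = 0.0 if record.attacks_avg_5y is None else record.attacks_avg_5y
    if avg >= t.cc2_severe_min:
        cc2 = SEVERE
    elif avg < t.cc2_mild_below:
        cc2 = MILD
    else:
        cc2 = INTERMEDIATE

    mx = 0.0 if record.attacks_max_year is None else record.attacks_max_year
    if mx > t.cc3_severe_above:
        cc3 = SEVERE
    elif mx < t.cc3_mild_below:
        cc3 = MILD
    else:
        cc3 = INTERMEDIATE

    last = 0.0 if record.attacks_last_year is None else record.attacks_last_year
    cc4 = SEVERE if last >= t.cc4_severe_min else MILD

    # CC5 applies only within the CC4 cohort; every classified patient is in
    # CC4 (S or M), so CC5 is always defined here.
    cc5 = "Y" if record.ltp else "N"

    return SeverityAssignment(
        patient_id=record.patient_id,
        cc1=cc1,
        cc2=cc2,
        cc3=cc3,
        cc4=cc4,
        cc5=cc5,
        asymptomatic=asymptomatic,
    )


def classify_cohort(
    records: Iterable[PatientRecord], thresholds: SeverityThresholds | None = None
) -> list[SeverityAssignment]:
    """Classify every patient record; controls are passed through silently skipped."""
    return [
        classify_patient(r, thresholds) for r in records if r.role == "patient"
    ]


_CC_ATTRIBUTE = {
    "cc1": "onset_age_years",
    "cc2": "attacks_avg_5y",
    "cc3": "attacks_max_year",
    "cc4": "attacks_last_year",
}


def summarize_subgroups(
    assignments: Iterable[SeverityAssignment],
    records: Iterable[PatientRecord],
) -> pd.DataFrame:
    """Per-criterion, per-side summary of the defining clinical attribute.

    Returns one row per (criterion, side) with n, median, min, max computed
    over the patients assigned severe or mild for that criterion.
    Asymptomatic patients count toward n but are excluded from the order
    statistics of CC1 (they have no onset age); their number is reported in
    ``n_asymptomatic``.  Empty subgroups yield n=0 with absent statistics.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("need at least one assigned patient")
    by_id = {r.patient_id: r for r in records}
    rows = []
    for cc, attr in _CC_ATTRIBUTE.items():
        for side in (SEVERE, MILD):
            members = [a for a in assignments if getattr(a, cc) == side]
            values = []
            n_asym = 0
            for a in members:
                rec = by_id[a.patient_id]
                v = getattr(rec, attr)
                if v is None:
                    n_asym += 1
                else:
                    values.append(float(v))
            s = pd.Series(values, dtype=float)
            rows.append(
                {
                    "criterion": cc,
                    "subgroup": f"{cc.upper()}-{side}",
                    "n": len(members),
                    "n_asymptomatic": n_asym,
                    "median": s.median() if len(s) else float("nan"),
                    "min": s.min() if len(s) else float("nan"),
                    "max": s.max() if len(s) else float("nan"),
                }
            )
    # CC5 rows: counts only, the attribute is categorical (treated or not).
    for side, label in (("Y", "CC5-Y"), ("N", "CC5-N")):
        members = [a for a in assignments if a.cc5 == side]
        rows.append(
            {
                "criterion": "cc5",
                "subgroup": label,
                "n": len(members),
                "n_asymptomatic": 0,
                "median": float("nan"),
                "min": float("nan"),
                "max": float("nan"),
            }
        )
    return pd.DataFrame(rows)


def assignments_frame(assignments: Iterable[SeverityAssignment]) -> pd.DataFrame:
    """Tabular view of assignments (one row per patient)."""
    return pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "cc1": a.cc1,
                "cc2": a.cc2,
                "cc3": a.cc3,
                "cc4": a.cc4,
                "cc5": a.cc5,
                "asymptomatic": a.asymptomatic,
            }
            for a in assignments
        ]
    )
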