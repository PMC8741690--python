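"""Eligibility and genetic-testing triage rules.

Children with diabetes onset between 6 months and 20 years are eligible.
Genetic testing is offered on genotype alone — a combination of the type 1
diabetes genetic risk score category and islet autoantibody status:

* low GRS            -> tested, irrespective of autoantibody status
* moderate GRS       -> tested only if autoantibody-negative
* high GRS           -> not tested

so that testing selects children with a high-to-moderate likelihood of
monogenic (rather than autoimmune) diabetes, independent of clinical
phenotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constants import AGE_MAX_YEARS, AGE_MIN_YEARS
from .grs import GrsResult

ANTIBODY_STATUSES = ("positive", "negative", "missing")

#: Controlled vocabulary of non-autoimmune extra-pancreatic feature codes.
FEATURE_VOCABULARY = frozenset(
    {
        "deafness",
        "anaemia",
        "developmental_delay",
        "optic_atrophy",
        "diabetes_insipidus",
        "liver_dysfunction",
        "skeletal_dysplasia",
        "microcephaly",
        "short_stature",
    }
)

TRIAGE_REASONS = (
    "low_grs",
    "moderate_ab_negative",
    "high_grs",
    "moderate_ab_positive",
    "moderate_ab_missing",
    "ineligible",
)
TESTED_REASONS = frozenset({"low_grs", "moderate_ab_negative"})


@dataclass
class ChildRecord:
    """One paediatric diabetes clinic attendee."""

    child_id: str
    age_at_diagnosis: float | None
    antibody_status: str  # positive / negative / missing
    insulin_treated: bool
    clinically_diagnosed_t1d: bool
    parent_with_diabetes: bool
    hba1c: float | None  # mmol/mol (IFCC)
    mody_probability: float | None = None  # composite clinical MODY probability
    parental_consanguinity: bool | None = None
    extra_pancreatic_features: frozenset[str] = field(default_factory=frozenset)
    grs: GrsResult | None = None

    def __post_init__(self) -> None:
        if self.antibody_status not in ANTIBODY_STATUSES:
            raise ValueError(f"{self.child_id}: bad antibody status {self.antibody_status!r}")
        if self.age_at_diagnosis is not None and self.age_at_diagnosis < 0:
            raise ValueError(f"{self.child_id}: negative age at diagnosis")
        if self.hba1c is not None and self.hba1c <= 0:
            raise ValueError(f"{self.child_id}: HbA1c must be positive")
        if self.mody_probability is not None and not 0 <= self.mody_probability <= 1:
            raise ValueError(f"{self.child_id}: MODY probability outside [0, 1]")
        bad = set(self.extra_pancreatic_features) - FEATURE_VOCABULARY
        if bad:
            raise ValueError(f"{self.child_id}: unknown feature codes {sorted(bad)}")
        self.extra_pancreatic_features = frozenset(self.extra_pancreatic_features)

    @property
    def hba1c_percent(self) -> float | None:
        """HbA1c on the DCCT percentage scale (display only)."""
        if self.hba1c is None:
            return None
        return self.hba1c / 10.929 + 2.15


@dataclass(frozen=True)
class TriageDecision:
    child_id: str
    tested: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in TRIAGE_REASONS:
            raise ValueError(f"unknown triage reason {self.reason!r}")
        if self.tested != (self.reason in TESTED_REASONS):
            raise ValueError(f"{self.child_id}: tested flag inconsistent with {self.reason}")


def filter_eligible(
    cohort: Iterable[ChildRecord],
) -> tuple[list[ChildRecord], list[tuple[ChildRecord, str]]]:
    """Split a cohort on the age-at-onset eligibility window (0.5-20 years,
    both bounds inclusive).  Records with missing age are excluded with an
    explicit reason rather than dropped silently."""
    eligible: list[ChildRecord] = []
    excluded: list[tuple[ChildRecord, str]] = []
    for rec in cohort:
        if rec.age_at_diagnosis is None:
            excluded.append((rec, "age_missing"))
        elif AGE_MIN_YEARS <= rec.age_at_diagnosis <= AGE_MAX_YEARS:
            eligible.append(rec)
        else:
            excluded.append((rec, "age_out_of_range"))
    return eligible, excluded


def is_definite_t1d(record: ChildRecord) -> bool:
    """Definite type 1 diabetes: clinically diagnosed, insulin treated and
    islet autoantibody-positive (a missing antibody result is not positive)."""
    return (
        record.clinically_diagnosed_t1d
        and record.insulin_treated
        and record.antibody_status == "positive"
    )


def select_for_testing(record: ChildRecord) -> TriageDecision:
    """Apply the GRS + autoantibody testing rule to one scored child."""
    if record.grs is None or record.grs.category is None:
        raise ValueError(
            f"{record.child_id}: no defined GRS category; score the child "
            "first (over-missing children stay flagged, not triaged)"
        )
    category = record.grs.category
    ab = record.antibody_status
    if category == "low":
        return TriageDecision(record.child_id, True, "low_grs")
    if category == "high":
        return TriageDecision(record.child_id, False, "high_grs")
    if ab == "negative":
        return TriageDecision(record.child_id, True, "moderate_ab_negative")
    if ab == "positive":
        return TriageDecision(record.child_id, False, "moderate_ab_positive")
    return TriageDecision(record.child_id, False, "moderate_ab_missing")


@dataclass(frozen=True)
class PartitionSummary:
    counts: dict[str, int]
    tested_total: int
    untested_total: int

    @property
    def total(self) -> int:
        return self.tested_total + self.untested_total


def partition_summary(decisions: Sequence[TriageDecision]) -> PartitionSummary:
    """Count decisions per reason; tested + untested always equals the
    number of decisions."""
    counts = Counter(d.reason for d in decisions)
    full = {reason: counts.get(reason, 0) for reason in TRIAGE_REASONS}
    tested = sum(1 for d in decisions if d.tested)
    return PartitionSummary(full, tested, len(decisions) - tested)
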