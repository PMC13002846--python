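"""Period stratification and cross-period comparison of comorbidity rules.

Patients are grouped into admission periods (default 2019-2020, 2021-2022,
2023-2024), rules are mined per period, merged into orientation-free
canonical patterns (X -> Y and Y -> X collapse to one pattern, since both
directions always share the same support), and period pairs are compared by
the Jaccard similarity of their top-k support-ranked pattern sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .arm_core import AssociationRule, RuleSet, rank_rules
from .ehr_coding import PatientRecord
from .errors import ComorbnetError

__all__ = [
    "PeriodDef",
    "CanonicalPattern",
    "PeriodComparison",
    "default_periods",
    "assign_period",
    "split_by_period",
    "canonical_pattern",
    "top_patterns",
    "jaccard_topk",
]


@dataclass(frozen=True)
class PeriodDef:
    """An inclusive admission-year range with a label, e.g. ``2019-2020``."""

    label: str
    year_min: int
    year_max: int

    def __post_init__(self):
        if self.year_min > self.year_max:
            raise ComorbnetError(
                f"period {self.label}: year_min {self.year_min} > year_max {self.year_max}"
            )

    def __contains__(self, year: int) -> bool:
        return self.year_min <= year <= self.year_max


def default_periods() -> list[PeriodDef]:
    """The three two-year admission periods of the study window."""
    return [
        PeriodDef("2019-2020", 2019, 2020),
        PeriodDef("2021-2022", 2021, 2022),
        PeriodDef("2023-2024", 2023, 2024),
    ]


def _validate_periods(periods: Sequence[PeriodDef]) -> None:
    ordered = sorted(periods, key=lambda p: p.year_min)
    for a, b in zip(ordered, ordered[1:]):
        if b.year_min <= a.year_max:
            raise ComorbnetError(f"periods {a.label} and {b.label} overlap")


def assign_period(
    record: PatientRecord,
    periods: Sequence[PeriodDef],
    policy: str = "first_admission",
) -> str | set[str]:
    """Map a patient to admission period(s).

    ``first_admission`` (default) assigns the single period of the earliest
    admission year, keeping each patient in exactly one period;
    ``per_admission`` returns the set of periods the patient's admissions
    touch. An admission year outside every period is rejected.
    """
    if policy not in ("first_admission", "per_admission"):
        raise ComorbnetError(f"unknown period policy: {policy!r}")
    _validate_periods(periods)
    if not record.admissions:
        raise ComorbnetError(f"patient {record.patient_id} has no admissions")

    def lookup(year: int) -> str:
        for p in periods:
            if year in p:
                return p.label
        raise ComorbnetError(
            f"admission year {year} (patient {record.patient_id}) outside all periods"
        )

    years = [y for y, _los in record.admissions]
    if policy == "first_admission":
        return lookup(min(years))
    return {lookup(y) for y in years}


def split_by_period(
    records: Sequence[PatientRecord],
    periods: Sequence[PeriodDef] | None = None,
    policy: str = "first_admission",
) -> dict[str, list[PatientRecord]]:
    """Partition records by period; every period label appears, possibly empty."""
    periods = list(periods) if periods is not None else default_periods()
    out: dict[str, list[PatientRecord]] = {p.label: [] for p in periods}
    for rec in records:
        assigned = assign_period(rec, periods, policy)
        labels = [assigned] if isinstance(assigned, str) else sorted(assigned)
        for label in labels:
            out[label].append(rec)
    return out


@dataclass(frozen=True)
class CanonicalPattern:
    """Orientation-free rule identity: sorted sides with side_a <= side_b."""

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise ComorbnetError("canonical pattern sides must be non-empty")
        if set(self.side_a) & set(self.side_b):
            raise ComorbnetError("canonical pattern sides must be disjoint")
        if self.side_a > self.side_b:
            raise ComorbnetError("canonical pattern sides must be ordered side_a <= side_b")

    def __str__(self) -> str:  # e.g. "B20+B37<->B99"
        return "+".join(self.side_a) + "<->" + "+".join(self.side_b)


@dataclass(frozen=True)
class PeriodComparison:
    period_a: str
    period_b: str
    jaccard: float
    top_k: int
    shared_patterns: tuple[CanonicalPattern, ...]


def canonical_pattern(rule: AssociationRule) -> CanonicalPattern:
    """Merge X -> Y and Y -> X into one orientation-free pattern."""
    x = tuple(sorted(rule.antecedent))
    y = tuple(sorted(rule.consequent))
    if x > y:
        x, y = y, x
    return CanonicalPattern(side_a=x, side_b=y)


def top_patterns(ruleset: RuleSet, k: int = 20) -> list[CanonicalPattern]:
    """Top-k canonical patterns by support.

    Rules are ranked by support (with deterministic tie-breaks), canonicalized
    in rank order, deduplicated, and the deduplicated list is cut to k
    patterns — so paired directions never consume two slots.
    """
    if k < 1:
        raise ComorbnetError(f"k must be >= 1, got {k}")
    seen: dict[CanonicalPattern, None] = {}
    for rule in rank_rules(ruleset, key="support"):
        pat = canonical_pattern(rule)
        if pat not in seen:
            seen[pat] = None
            if len(seen) == k:
                break
    return list(seen)


def jaccard_topk(rules_p1: RuleSet, rules_p2: RuleSet, k: int = 20) -> PeriodComparison:
    """Jaccard similarity of the two periods' top-k canonical pattern sets."""
    if rules_p1.config != rules_p2.config:
        raise ComorbnetError("period rule sets were mined with different configs")
    set_a = set(top_patterns(rules_p1, k))
    set_b = set(top_patterns(rules_p2, k))
    union = set_a | set_b
    if not union:
        raise ComorbnetError("both canonical pattern sets are empty; Jaccard undefined")
    shared = set_a & set_b
    return PeriodComparison(
        period_a="a",
        period_b="b",
        jaccard=len(shared) / len(union),
        top_k=k,
        shared_patterns=tuple(sorted(shared, key=str)),
    )
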