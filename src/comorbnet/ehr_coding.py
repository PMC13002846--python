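"""Ingestion and coding of inpatient ICD-10 diagnosis records.

Raw hospital diagnosis rows (one row per patient-admission-diagnosis) are
normalized to 3-character ICD-10 categories (first letter + two digits),
filtered by chapter-level exclusion rules, consolidated into per-patient
records, and turned into the transaction sets that itemset mining and
network construction consume.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ComorbnetError, MalformedCodeError

__all__ = [
    "DiagnosisRow",
    "PatientRecord",
    "TransactionSet",
    "ExclusionPolicy",
    "normalize_code",
    "filter_exclusions",
    "ingest_rows",
    "build_transactions",
    "assign_who_stage",
    "comorbidity_count",
    "load_stage_map",
    "write_transactions_csv",
    "read_transactions_csv",
    "DIAGNOSIS_COLUMNS",
]

#: Required columns of a diagnosis CSV, in canonical order.
DIAGNOSIS_COLUMNS = [
    "patient_id",
    "admission_id",
    "year",
    "gender",
    "age",
    "residence",
    "los_days",
    "icd10_code",
]

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


@dataclass(frozen=True)
class DiagnosisRow:
    """One raw diagnosis assignment within one admission."""

    patient_id: str
    admission_id: str
    year: int
    gender: str
    age: float
    residence: str
    los_days: float
    raw_code: str


@dataclass
class PatientRecord:
    """A consolidated patient: demographics, admissions, aggregated categories.

    ``categories`` holds the 3-character ICD-10 categories retained after
    normalization and exclusion filtering. ``who_stage`` is the WHO clinical
    stage proxy (1 when no stage-defining category is present) and
    ``n_comorbidities`` the retained-category count net of any configured
    index-disease codes.
    """

    patient_id: str
    gender: str
    age: float
    residence: str
    admissions: list[tuple[int, float]] = field(default_factory=list)
    categories: frozenset[str] = frozenset()
    admission_categories: list[frozenset[str]] = field(default_factory=list)
    who_stage: int = 1
    n_comorbidities: int = 0


@dataclass(frozen=True)
class TransactionSet:
    """Transactions for itemset mining: one category set per patient/admission."""

    transactions: tuple[tuple[str, frozenset[str]], ...]
    universe: tuple[str, ...]
    n: int

    def __post_init__(self):
        if self.n != len(self.transactions):
            raise ComorbnetError("transaction count n does not match list length")


def normalize_code(raw_code: str) -> str:
    """Aggregate a raw ICD-10 code to its 3-character category.

    Uppercases, strips whitespace, drops any dot suffix, and truncates
    supplementary characters beyond position 3 (``"B20.7"`` -> ``"B20"``,
    ``"e87"`` -> ``"E87"``). Raises :class:`MalformedCodeError` when the
    result is not letter-then-two-digits.
    """
    if not raw_code or not str(raw_code).strip():
        raise MalformedCodeError(raw_code)
    code = str(raw_code).strip().upper().replace(" ", "")
    code = code.split(".", 1)[0][:3]
    if not _CATEGORY_RE.match(code):
        raise MalformedCodeError(raw_code)
    return code


def _expand_prefixes(prefixes: Iterable[str]) -> frozenset[str]:
    letters: set[str] = set()
    for pref in prefixes:
        pref = pref.strip().upper()
        if len(pref) == 1 and pref.isalpha():
            letters.add(pref)
        elif len(pref) == 3 and pref[1] == "-" and pref[0].isalpha() and pref[2].isalpha():
            lo, hi = sorted((pref[0], pref[2]))
            letters.update(chr(c) for c in range(ord(lo), ord(hi) + 1))
        else:
            raise ComorbnetError(
                f"exclusion prefix must be a letter or letter range: {pref!r}"
            )
    return frozenset(letters)


@dataclass(frozen=True)
class ExclusionPolicy:
    """Chapter-level exclusions, given as single letters or ranges like ``V-Y``.

    The default drops mental disorders (F), injuries and external causes
    (S, T and V through Y) and congenital conditions (Q).
    """

    excluded_chapters: frozenset[str] = frozenset({"F", "Q", "S", "T", "V-Y"})

    @property
    def letters(self) -> frozenset[str]:
        return _expand_prefixes(self.excluded_chapters)


DEFAULT_EXCLUSION = ExclusionPolicy()


def filter_exclusions(
    categories: Iterable[str], policy: ExclusionPolicy = DEFAULT_EXCLUSION
) -> frozenset[str]:
    """Drop every category whose chapter letter falls in the policy."""
    letters = policy.letters
    return frozenset(c for c in categories if c[0] not in letters)


def assign_who_stage(categories: Iterable[str], stage_map: Mapping[str, int]) -> int:
    """WHO clinical stage proxy: max mapped stage over the patient's categories.

    Returns 1 when no category is stage-defining. Stage-map values outside
    {2, 3, 4} are rejected.
    """
    bad = {v for v in stage_map.values() if v not in (2, 3, 4)}
    if bad:
        raise ComorbnetError(f"stage map values must be in {{2,3,4}}, got {sorted(bad)}")
    stages = [stage_map[c] for c in categories if c in stage_map]
    return max(stages, default=1)


def comorbidity_count(categories: Iterable[str], index_codes: Iterable[str] = ()) -> int:
    """Number of retained categories excluding any index-disease codes."""
    return len(frozenset(categories) - frozenset(index_codes))


def load_stage_map(path: str | Path | None = None) -> dict[str, int]:
    """Load a category -> WHO stage CSV (columns ``category,stage``).

    Without a path, loads the editable default resource shipped with the
    package (an illustrative mapping derived from WHO clinical staging
    guidance; sites should review and adapt it).
    """
    if path is None:
        path = Path(__file__).parent / "data" / "who_stage_map.csv"
    mapping: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            mapping[normalize_code(row["category"])] = int(row["stage"])
    bad = {v for v in mapping.values() if v not in (2, 3, 4)}
    if bad:
        raise ComorbnetError(f"stage map values must be in {{2,3,4}}, got {sorted(bad)}")
    return mapping


def ingest_rows(
    rows: pd.DataFrame,
    policy: ExclusionPolicy = DEFAULT_EXCLUSION,
    stage_map: Mapping[str, int] | None = None,
    index_codes: Iterable[str] = (),
) -> list[PatientRecord]:
    """Consolidate diagnosis rows into per-patient records.

    Codes are normalized and chapter-filtered; patients whose retained
    category set is empty are dropped. Demographics are taken from the
    patient's first row; admissions are the distinct ``admission_id`` values
    with their year and length of stay.
    """
    missing = [c for c in DIAGNOSIS_COLUMNS if c not in rows.columns]
    if missing:
        raise ComorbnetError(f"diagnosis table missing columns: {missing}")
    if len(rows) == 0:
        raise ComorbnetError("diagnosis table is empty")

    index_codes = frozenset(index_codes)
    records: list[PatientRecord] = []
    for pid, grp in rows.groupby("patient_id", sort=True):
        first = grp.iloc[0]
        admissions: dict[str, tuple[int, float]] = {}
        adm_cats: dict[str, set[str]] = {}
        for row in grp.itertuples(index=False):
            aid = str(row.admission_id)
            admissions.setdefault(aid, (int(row.year), float(row.los_days)))
            adm_cats.setdefault(aid, set()).add(normalize_code(row.icd10_code))
        order = sorted(admissions, key=lambda a: (admissions[a], a))
        per_adm = [filter_exclusions(adm_cats[a], policy) for a in order]
        retained = frozenset().union(*per_adm)
        if not retained:
            continue
        rec = PatientRecord(
            patient_id=str(pid),
            gender=str(first["gender"]),
            age=float(first["age"]),
            residence=str(first["residence"]),
            admissions=[admissions[a] for a in order],
            categories=retained,
            admission_categories=per_adm,
            n_comorbidities=comorbidity_count(retained, index_codes),
        )
        if stage_map is not None:
            rec.who_stage = assign_who_stage(retained, stage_map)
        records.append(rec)
    return records


def build_transactions(
    records: Sequence[PatientRecord], level: str = "patient"
) -> TransactionSet:
    """Build the mining transaction set at patient or admission granularity.

    ``patient`` (default): one transaction per patient, the union of its
    categories across admissions — matching per-patient comorbidity
    counting. ``admission``: one transaction per admission, each carrying
    only that admission's categories.
    """
    if not records:
        raise ComorbnetError("cannot build transactions from an empty record collection")
    if level not in ("patient", "admission"):
        raise ComorbnetError(f"unknown transaction level: {level!r}")
    txns: list[tuple[str, frozenset[str]]] = []
    for rec in records:
        if level == "patient":
            txns.append((rec.patient_id, rec.categories))
        else:
            per_adm = rec.admission_categories or [rec.categories] * len(rec.admissions)
            for i, cats in enumerate(per_adm):
                txns.append((f"{rec.patient_id}#{i}", cats))
    universe = tuple(sorted(set().union(*(s for _, s in txns))))
    return TransactionSet(transactions=tuple(txns), universe=universe, n=len(txns))


def write_transactions_csv(ts: TransactionSet, path: str | Path) -> None:
    """Write transactions as ``transaction_id,categories`` (semicolon-joined)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["transaction_id", "categories"])
        for tid, items in ts.transactions:
            writer.writerow([tid, ";".join(sorted(items))])


def read_transactions_csv(path: str | Path) -> TransactionSet:
    """Read a transactions CSV written by :func:`write_transactions_csv`."""
    txns: list[tuple[str, frozenset[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            items = frozenset(c for c in row["categories"].split(";") if c)
            txns.append((row["transaction_id"], items))
    if not txns:
        raise ComorbnetError(f"no transactions found in {path}")
    universe = tuple(sorted(set().union(*(s for _, s in txns))))
    return TransactionSet(transactions=tuple(txns), universe=universe, n=len(txns))
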