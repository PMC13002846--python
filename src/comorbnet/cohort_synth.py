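"""Synthetic inpatient cohort generation with planted comorbidity structure.

The generator uses a noisy-OR latent-block model. Each patient independently
joins each comorbidity block ``b`` with probability ``pi_b``; given the
joined blocks, disease category ``i`` is present with probability

    P(i | z) = 1 - (1 - p_i) * prod_{b: z_b = 1, i in b} (1 - q_{b,i})

where ``p_i`` is the background prevalence. Block membership plants positive
pairwise (and higher-order) associations among member categories, while
closed-form one- and two-item expectations (:func:`expected_support`) make
the planted structure analytically checkable — the recovery target for the
rule miner.

Admission years come from a period mixture, demographics are independent of
the disease process, and per-patient admission counts follow a shifted
geometric. :func:`study_spec` builds the default cohort emulating an
HIV-inpatient comorbidity study: ~3,000 patients, ~600 long-tail disease
categories, hub blocks of co-occurring infection/metabolic categories, and a
right-skewed per-patient category count (median about 9, quartiles about
7 and 13).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ehr_coding import DIAGNOSIS_COLUMNS, PatientRecord
from .errors import SpecError

__all__ = [
    "ComorbidityBlock",
    "Demographics",
    "SyntheticCohortSpec",
    "PlantedTruth",
    "generate_cohort",
    "expected_support",
    "planted_truth",
    "cohort_to_rows",
    "simulate_rows",
    "write_cohort_csv",
    "study_spec",
    "spec_from_yaml",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise SpecError(f"{name} must be a probability in [0,1], got {value}")


@dataclass(frozen=True)
class ComorbidityBlock:
    """A latent cluster of co-occurring disease categories.

    ``membership_prob`` is the probability a patient belongs to the block;
    ``item_probs`` maps each member category to its conditional activation
    probability given membership.
    """

    block_id: str
    membership_prob: float
    item_probs: Mapping[str, float]

    def __post_init__(self):
        _check_prob(f"block {self.block_id} membership_prob", self.membership_prob)
        if not self.item_probs:
            raise SpecError(f"block {self.block_id} has an empty item set")
        for item, q in self.item_probs.items():
            _check_prob(f"block {self.block_id} item_probs[{item}]", q)


@dataclass(frozen=True)
class Demographics:
    """Marginal demographic distributions, independent of the disease process."""

    male_prob: float = 0.727
    rural_prob: float = 0.787
    #: (low, high, weight) age brackets; ages drawn uniformly within a bracket.
    age_brackets: tuple[tuple[float, float, float], ...] = (
        (0, 20, 0.005),
        (20, 40, 0.176),
        (40, 60, 0.502),
        (60, 90, 0.317),
    )
    #: success probability of the shifted geometric admission count (mean 1/p).
    admission_geom_p: float = 0.5
    #: lognormal length-of-stay parameters (days).
    los_meanlog: float = 2.237
    los_sdlog: float = 0.552

    def __post_init__(self):
        _check_prob("male_prob", self.male_prob)
        _check_prob("rural_prob", self.rural_prob)
        if not 0 < self.admission_geom_p <= 1:
            raise SpecError(f"admission_geom_p must be in (0,1], got {self.admission_geom_p}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full generative model for one synthetic cohort.

    ``period_weights`` maps period labels (``"2019"`` or ``"2019-2020"``) to
    mixing probabilities summing to 1; a patient's admission years are drawn
    uniformly within their assigned period.
    """

    n_patients: int
    background_prevalence: Mapping[str, float]
    blocks: tuple[ComorbidityBlock, ...] = ()
    period_weights: Mapping[str, float] = field(
        default_factory=lambda: {"2019-2024": 1.0}
    )
    demographics: Demographics = Demographics()
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise SpecError(f"n_patients must be positive, got {self.n_patients}")
        for item, p in self.background_prevalence.items():
            _check_prob(f"background_prevalence[{item}]", p)
        universe = set(self.background_prevalence)
        for block in self.blocks:
            missing = set(block.item_probs) - universe
            if missing:
                raise SpecError(
                    f"block {block.block_id} items not in category universe: "
                    f"{sorted(missing)}"
                )
        total = sum(self.period_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"period_weights must sum to 1, got {total}")
        for label in self.period_weights:
            _parse_period_label(label)

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(sorted(self.background_prevalence))


@dataclass(frozen=True)
class PlantedTruth:
    """Closed-form expectations planted by a spec: the miner's recovery target."""

    marginal_supports: dict[str, float]
    pair_supports: dict[frozenset[str], float]
    positive_pairs: frozenset[frozenset[str]]


def _parse_period_label(label: str) -> tuple[int, int]:
    parts = str(label).replace("–", "-").split("-")
    try:
        if len(parts) == 1:
            y = int(parts[0])
            return y, y
        if len(parts) == 2:
            lo, hi = int(parts[0]), int(parts[1])
            if lo > hi:
                raise ValueError
            return lo, hi
    except ValueError:
        pass
    raise SpecError(f"period label must be 'YYYY' or 'YYYY-YYYY', got {label!r}")


def expected_support(spec: SyntheticCohortSpec, items: Iterable[str]) -> float:
    """Exact expectation of a 1- or 2-item support under the noisy-OR model.

    Uses conditional independence of items given block memberships:
    for a single item ``i``,

        P(i) = 1 - (1 - p_i) * prod_b (1 - pi_b * q_{b,i})

    and for a pair, expanding the product of the two noisy-OR failures,

        P(i ^ j) = 1 - F_i - F_j
                   + (1-p_i)(1-p_j) * prod_b (1 - pi_b * (q_i + q_j - q_i q_j))

    where ``F_i = (1-p_i) * prod_b (1 - pi_b q_{b,i})`` is the marginal
    failure probability.
    """
    items = tuple(sorted(set(items)))
    if not 1 <= len(items) <= 2:
        raise SpecError(f"expected_support handles 1 or 2 items, got {len(items)}")
    for item in items:
        if item not in spec.background_prevalence:
            raise SpecError(f"item {item!r} not in the category universe")

    def marginal_failure(i: str) -> float:
        f = 1.0 - spec.background_prevalence[i]
        for b in spec.blocks:
            q = b.item_probs.get(i, 0.0)
            f *= 1.0 - b.membership_prob * q
        return f

    if len(items) == 1:
        return 1.0 - marginal_failure(items[0])

    i, j = items
    f_i, f_j = marginal_failure(i), marginal_failure(j)
    joint_failure = (1.0 - spec.background_prevalence[i]) * (
        1.0 - spec.background_prevalence[j]
    )
    for b in spec.blocks:
        qi = b.item_probs.get(i, 0.0)
        qj = b.item_probs.get(j, 0.0)
        joint_failure *= 1.0 - b.membership_prob * (qi + qj - qi * qj)
    return 1.0 - f_i - f_j + joint_failure


def planted_truth(spec: SyntheticCohortSpec) -> PlantedTruth:
    """Enumerate expectations for all singletons and all within-block pairs."""
    marginals = {i: expected_support(spec, [i]) for i in spec.universe}
    pairs: dict[frozenset[str], float] = {}
    for block in spec.blocks:
        members = sorted(block.item_probs)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                key = frozenset((members[a_idx], members[b_idx]))
                if key not in pairs:
                    pairs[key] = expected_support(spec, key)
    positive = frozenset(
        key
        for key, p_joint in pairs.items()
        if p_joint > math.prod(marginals[i] for i in key) + 1e-12
    )
    return PlantedTruth(
        marginal_supports=marginals, pair_supports=pairs, positive_pairs=positive
    )


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """Draw a cohort of consolidated patient records, reproducibly from the seed.

    Disease categories are drawn at patient level from the noisy-OR model;
    admission years from the period mixture; each category is then scattered
    uniformly across the patient's admissions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    universe = list(spec.universe)
    m = len(universe)
    col = {item: idx for idx, item in enumerate(universe)}

    p_bg = np.array([spec.background_prevalence[i] for i in universe])
    fail = np.broadcast_to(1.0 - p_bg, (n, m)).copy()
    for block in spec.blocks:
        member = rng.random(n) < block.membership_prob
        for item, q in block.item_probs.items():
            fail[member, col[item]] *= 1.0 - q
    present = rng.random((n, m)) < (1.0 - fail)

    demo = spec.demographics
    male = rng.random(n) < demo.male_prob
    rural = rng.random(n) < demo.rural_prob
    brackets = demo.age_brackets
    weights = np.array([w for _lo, _hi, w in brackets], dtype=float)
    weights /= weights.sum()
    bracket_idx = rng.choice(len(brackets), size=n, p=weights)
    age_u = rng.random(n)
    ages = np.array(
        [
            brackets[k][0] + age_u[i] * (brackets[k][1] - brackets[k][0])
            for i, k in enumerate(bracket_idx)
        ]
    )

    labels = list(spec.period_weights)
    period_p = np.array([spec.period_weights[lab] for lab in labels], dtype=float)
    period_p /= period_p.sum()
    period_idx = rng.choice(len(labels), size=n, p=period_p)
    n_adm = rng.geometric(demo.admission_geom_p, size=n)  # shifted geometric, >= 1

    pad = len(str(n))
    records: list[PatientRecord] = []
    for i in range(n):
        cats = frozenset(universe[j] for j in np.nonzero(present[i])[0])
        lo, hi = _parse_period_label(labels[period_idx[i]])
        years = sorted(int(y) for y in rng.integers(lo, hi + 1, size=int(n_adm[i])))
        los = np.round(
            np.exp(rng.normal(demo.los_meanlog, demo.los_sdlog, size=len(years))), 1
        )
        adm_assign = rng.integers(0, len(years), size=len(cats))
        per_adm: list[set[str]] = [set() for _ in years]
        for cat, a in zip(sorted(cats), adm_assign):
            per_adm[a].add(cat)
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{pad}d}",
                gender="male" if male[i] else "female",
                age=float(np.round(ages[i], 1)),
                residence="rural" if rural[i] else "urban",
                admissions=[(y, float(l)) for y, l in zip(years, los)],
                categories=cats,
                admission_categories=[frozenset(s) for s in per_adm],
                n_comorbidities=len(cats),
            )
        )
    return records


def cohort_to_rows(records: Sequence[PatientRecord], seed: int = 0) -> pd.DataFrame:
    """Expand patient records into raw diagnosis rows (one per admission-diagnosis).

    A random fraction of codes is emitted with a dotted subcode suffix
    (``B20.3``) to exercise downstream normalization. Admissions with no
    assigned category still contribute a row for one of the patient's
    categories so that every admission appears in the output.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for rec in records:
        per_adm = [set(s) for s in rec.admission_categories]
        for a, cats in enumerate(per_adm):
            if not cats and rec.categories:
                cats = {sorted(rec.categories)[int(rng.integers(len(rec.categories)))]}
            year, los = rec.admissions[a]
            for cat in sorted(cats):
                raw = cat
                if rng.random() < 0.35:
                    raw = f"{cat}.{int(rng.integers(0, 10))}"
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "admission_id": f"{rec.patient_id}-A{a + 1}",
                        "year": year,
                        "gender": rec.gender,
                        "age": rec.age,
                        "residence": rec.residence,
                        "los_days": los,
                        "icd10_code": raw,
                    }
                )
    return pd.DataFrame(rows, columns=DIAGNOSIS_COLUMNS)


def simulate_rows(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate a cohort and expand it to diagnosis rows in one step."""
    records = generate_cohort(spec)
    return cohort_to_rows(records, seed=spec.seed + 1)


def write_cohort_csv(spec: SyntheticCohortSpec, path: str | Path) -> pd.DataFrame:
    """Simulate diagnosis rows and write them as the ingestion CSV."""
    rows = simulate_rows(spec)
    rows.to_csv(path, index=False)
    return rows


# ---------------------------------------------------------------------------
# Default study cohort
# ---------------------------------------------------------------------------

def _hub_background() -> dict[str, float]:
    """Hub backgrounds: the most prevalent infection/metabolic categories."""
    base = {
        "E87": 0.55,
        "B20": 0.30,
        "B37": 0.28,
        "E46": 0.28,
        "D64": 0.30,
        "B99": 0.14,
        "J18": 0.16,
        "B49": 0.10,
        "B59": 0.08,
        "N19": 0.10,
        "B48": 0.07,
        "K72": 0.08,
        "A15": 0.09,
        "K29": 0.14,
        "J84": 0.06,
        "B34": 0.08,
        "K76": 0.12,
        "B25": 0.06,
        "K73": 0.07,
        "D70": 0.10,
        "D69": 0.09,
        "E79": 0.07,
        "J90": 0.08,
        "E78": 0.07,
        "N20": 0.06,
    }
    return base


_STUDY_BLOCKS: tuple[ComorbidityBlock, ...] = (
    ComorbidityBlock(
        block_id="immunosuppression",
        membership_prob=0.55,
        item_probs={
            "B20": 0.75,
            "B37": 0.70,
            "B99": 0.40,
            "B49": 0.25,
            "B59": 0.18,
            "A15": 0.15,
            "B48": 0.12,
            "B25": 0.10,
        },
    ),
    ComorbidityBlock(
        block_id="metabolic",
        membership_prob=0.60,
        item_probs={
            "E87": 0.75,
            "E46": 0.65,
            "D64": 0.55,
            "D70": 0.18,
            "D69": 0.12,
        },
    ),
    ComorbidityBlock(
        block_id="respiratory",
        membership_prob=0.25,
        item_probs={
            "J18": 0.60,
            "E87": 0.35,
            "E46": 0.25,
            "J90": 0.20,
            "J84": 0.12,
        },
    ),
    # A minority of severely ill patients accumulating many organ-system
    # complications: this block supplies the long right tail of the
    # per-patient count distribution.
    ComorbidityBlock(
        block_id="advanced_disease",
        membership_prob=0.28,
        item_probs={
            "N19": 0.35,
            "K72": 0.35,
            "B48": 0.30,
            "A15": 0.30,
            "J84": 0.25,
            "B34": 0.30,
            "K76": 0.30,
            "B25": 0.30,
            "K73": 0.25,
            "D70": 0.35,
            "D69": 0.30,
            "E79": 0.25,
            "J90": 0.30,
            "E78": 0.25,
            "N20": 0.20,
            "B59": 0.30,
            "B49": 0.30,
            "K29": 0.30,
        },
    ),
)

#: Admission-period mixture matching the study's per-year admission shares.
_STUDY_PERIOD_WEIGHTS: dict[str, float] = {
    "2019": 0.1953,
    "2020": 0.1709,
    "2021": 0.1965,
    "2022": 0.1819,
    "2023": 0.1596,
    "2024": 0.0958,
}

#: Low-prevalence excluded-chapter codes included to exercise chapter filtering.
_EXCLUDED_CHAPTER_CODES: dict[str, float] = {
    "F32": 0.02,
    "F20": 0.01,
    "Q21": 0.005,
    "S72": 0.01,
    "T78": 0.01,
    "V01": 0.003,
    "X59": 0.003,
}


def _filler_categories(n_fillers: int) -> dict[str, float]:
    """Long-tail filler prevalences p_k ~ 0.55/(k+6), over non-excluded chapters."""
    letters = "ABCDEGHIJKLMNR"
    hubs = set(_hub_background())
    cats: dict[str, float] = {}
    k = 0
    for num in range(100):
        for letter in letters:
            code = f"{letter}{num:02d}"
            if code in hubs or code in cats:
                continue
            cats[code] = min(0.55 / (k + 6), 0.15)
            k += 1
            if k >= n_fillers:
                return cats
    raise SpecError("filler universe exhausted")


def study_spec(
    n_patients: int = 3000, seed: int = 0, n_fillers: int = 575
) -> SyntheticCohortSpec:
    """The default synthetic study cohort.

    ~3,000 patients over ~600 disease categories: 25 hub categories carrying
    three noisy-OR blocks (immunosuppression, metabolic, respiratory), a
    long-tail filler background, a handful of excluded-chapter codes, and the
    six-year admission mixture. Calibrated once to a right-skewed per-patient
    category count with median about 9 and quartiles near 7 and 13.
    """
    background = _hub_background()
    background.update(_filler_categories(n_fillers))
    background.update(_EXCLUDED_CHAPTER_CODES)
    return SyntheticCohortSpec(
        n_patients=n_patients,
        background_prevalence=background,
        blocks=_STUDY_BLOCKS,
        period_weights=_STUDY_PERIOD_WEIGHTS,
        demographics=Demographics(),
        seed=seed,
    )


def spec_from_yaml(path: str | Path) -> SyntheticCohortSpec:
    """Load a :class:`SyntheticCohortSpec` from a YAML config.

    Expected keys: ``n_patients``, ``background_prevalence`` (mapping),
    ``blocks`` (list of ``{block_id, membership_prob, item_probs}``),
    ``period_weights``, ``seed`` and optionally ``demographics``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SpecError(f"cohort spec YAML must be a mapping, got {type(raw).__name__}")
    blocks = tuple(
        ComorbidityBlock(
            block_id=str(b["block_id"]),
            membership_prob=float(b["membership_prob"]),
            item_probs={str(k): float(v) for k, v in b["item_probs"].items()},
        )
        for b in raw.get("blocks", [])
    )
    demo = Demographics(**raw["demographics"]) if "demographics" in raw else Demographics()
    return SyntheticCohortSpec(
        n_patients=int(raw["n_patients"]),
        background_prevalence={
            str(k): float(v) for k, v in raw["background_prevalence"].items()
        },
        blocks=blocks,
        period_weights={str(k): float(v) for k, v in raw.get("period_weights", {"2019-2024": 1.0}).items()},
        demographics=demo,
        seed=int(raw.get("seed", 0)),
    )
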