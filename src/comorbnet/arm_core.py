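"""Apriori frequent-itemset mining and association-rule generation.

Implements level-wise Apriori with prefix-join candidate generation and
subset pruning, an exhaustive brute-force enumerator used as an independent
oracle in the test suite, and the five rule metrics (support, confidence,
lift, leverage, conviction) with the threshold filtering used for
comorbidity pattern mining: minimum support 0.20, minimum confidence 0.20,
lift >= 1.0, maximum itemset length 4.

Rules are emitted in both directions (X -> Y and Y -> X), mirroring how
comorbidity rule tables list them; orientation-free deduplication lives in
:mod:`comorbnet.temporal_compare`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .ehr_coding import TransactionSet
from .errors import ComorbnetError

__all__ = [
    "MiningConfig",
    "FrequentItemset",
    "AssociationRule",
    "RuleMetrics",
    "RuleSet",
    "mine_frequent",
    "brute_force_frequent",
    "rule_metrics",
    "generate_rules",
    "rank_rules",
    "mine_rules",
    "round_half_away",
    "itemsets_to_frame",
    "rules_to_frame",
]

_EPS = 1e-12


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for mining: support/confidence fractions, lift floor, max length."""

    min_support: float = 0.20
    min_confidence: float = 0.20
    min_lift: float = 1.0
    max_len: int = 4

    def __post_init__(self):
        if not 0.0 < self.min_support <= 1.0:
            raise ComorbnetError(f"min_support must be in (0,1], got {self.min_support}")
        if not 0.0 < self.min_confidence <= 1.0:
            raise ComorbnetError(
                f"min_confidence must be in (0,1], got {self.min_confidence}"
            )
        if self.min_lift < 0:
            raise ComorbnetError(f"min_lift must be non-negative, got {self.min_lift}")
        if self.max_len < 2:
            raise ComorbnetError(f"max_len must be >= 2, got {self.max_len}")


@dataclass(frozen=True)
class FrequentItemset:
    items: tuple[str, ...]
    support: float
    count: int


@dataclass(frozen=True)
class RuleMetrics:
    confidence: float
    lift: float
    leverage: float
    conviction: float


@dataclass(frozen=True)
class AssociationRule:
    """X -> Y with its five metrics. ``conviction`` is ``math.inf`` at confidence 1."""

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support_antecedent: float
    support_consequent: float
    support: float
    confidence: float
    lift: float
    leverage: float
    conviction: float


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[AssociationRule, ...]
    config: MiningConfig
    n: int


def _sort_key(itemset: FrequentItemset):
    return (len(itemset.items), -itemset.support, itemset.items)


def mine_frequent(
    transactions: TransactionSet, config: MiningConfig = MiningConfig()
) -> list[FrequentItemset]:
    """Level-wise Apriori over the transaction set.

    L1 comes from singleton counts; level-(k+1) candidates join two frequent
    k-itemsets sharing a (k-1)-prefix and are pruned when any (k-1)-subset is
    infrequent. Support counting uses per-item transaction bitsets with
    intersection popcounts. Output is sorted by (size, descending support,
    lexicographic items).
    """
    n = transactions.n
    if n < 1:
        raise ComorbnetError("cannot mine an empty transaction set")
    min_count = config.min_support * n - 1e-9

    item_bits: dict[str, int] = {item: 0 for item in transactions.universe}
    for t_idx, (_tid, items) in enumerate(transactions.transactions):
        bit = 1 << t_idx
        for item in items:
            item_bits[item] |= bit

    results: list[FrequentItemset] = []
    level: dict[tuple[str, ...], int] = {}
    for item in transactions.universe:
        count = item_bits[item].bit_count()
        if count >= min_count:
            level[(item,)] = item_bits[item]
            results.append(FrequentItemset((item,), count / n, count))

    k = 1
    while level and k < config.max_len:
        prev_keys = sorted(level)
        prev_set = set(prev_keys)
        nxt: dict[tuple[str, ...], int] = {}
        for i, a in enumerate(prev_keys):
            for b in prev_keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: once prefixes diverge, no later match
                cand = a + (b[-1],)
                # downward-closure prune: every (k)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in prev_set for j in range(len(cand))
                ):
                    continue
                bits = level[a] & item_bits[cand[-1]]
                count = bits.bit_count()
                if count >= min_count:
                    nxt[cand] = bits
                    results.append(FrequentItemset(cand, count / n, count))
        level = nxt
        k += 1

    results.sort(key=_sort_key)
    return results


def brute_force_frequent(
    transactions: TransactionSet, config: MiningConfig = MiningConfig()
) -> list[FrequentItemset]:
    """Exhaustive enumeration oracle: every subset up to max_len, counted directly.

    Guarded to universes of at most 20 items; same ordering contract as
    :func:`mine_frequent`.
    """
    if len(transactions.universe) > 20:
        raise ComorbnetError(
            f"brute force guarded to <=20 items, got {len(transactions.universe)}"
        )
    n = transactions.n
    if n < 1:
        raise ComorbnetError("cannot mine an empty transaction set")
    min_count = config.min_support * n - 1e-9
    results = []
    sets = [items for _tid, items in transactions.transactions]
    for size in range(1, min(config.max_len, len(transactions.universe)) + 1):
        for cand in combinations(transactions.universe, size):
            cset = frozenset(cand)
            count = sum(1 for s in sets if cset <= s)
            if count >= min_count:
                results.append(FrequentItemset(tuple(cand), count / n, count))
    results.sort(key=_sort_key)
    return results


def rule_metrics(s: float, s_x: float, s_y: float) -> RuleMetrics:
    """Confidence, lift, leverage and conviction from the three supports.

    confidence = s / s_X;  lift = s / (s_X * s_Y);  leverage = s - s_X * s_Y;
    conviction = (1 - s_Y) / (1 - confidence), infinite when confidence = 1.
    """
    if not 0 < s_x <= 1 or not 0 < s_y <= 1:
        raise ComorbnetError(f"antecedent/consequent supports must be in (0,1]: {s_x}, {s_y}")
    if s < 0 or s > min(s_x, s_y) + _EPS:
        raise ComorbnetError(
            f"joint support {s} inconsistent with marginals {s_x}, {s_y}"
        )
    confidence = s / s_x
    lift = s / (s_x * s_y)
    leverage = s - s_x * s_y
    if confidence >= 1.0 - _EPS:
        conviction = math.inf
    else:
        conviction = (1.0 - s_y) / (1.0 - confidence)
    return RuleMetrics(confidence, lift, leverage, conviction)


def generate_rules(
    frequent: Sequence[FrequentItemset], config: MiningConfig, n: int
) -> RuleSet:
    """Every bipartition of every frequent itemset of size >= 2, both directions.

    Downward closure guarantees every side's support is available from the
    frequent list. Rules failing the confidence or lift thresholds are
    dropped.
    """
    support: dict[tuple[str, ...], float] = {fi.items: fi.support for fi in frequent}
    rules: list[AssociationRule] = []
    for fi in frequent:
        if len(fi.items) < 2:
            continue
        items = fi.items
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                cons = tuple(i for i in items if i not in ante)
                try:
                    s_x = support[ante]
                    s_y = support[cons]
                except KeyError as exc:  # pragma: no cover - closure violation
                    raise ComorbnetError(
                        f"missing subset support for {exc.args[0]}"
                    ) from exc
                m = rule_metrics(fi.support, s_x, s_y)
                if m.confidence >= config.min_confidence - _EPS and m.lift >= config.min_lift - _EPS:
                    rules.append(
                        AssociationRule(
                            antecedent=ante,
                            consequent=cons,
                            support_antecedent=s_x,
                            support_consequent=s_y,
                            support=fi.support,
                            confidence=m.confidence,
                            lift=m.lift,
                            leverage=m.leverage,
                            conviction=m.conviction,
                        )
                    )
    rules.sort(key=lambda r: (-r.support, -r.lift, r.antecedent, r.consequent))
    return RuleSet(rules=tuple(rules), config=config, n=n)


def mine_rules(
    transactions: TransactionSet, config: MiningConfig = MiningConfig()
) -> RuleSet:
    """Convenience: mine frequent itemsets then generate filtered rules."""
    frequent = mine_frequent(transactions, config)
    return generate_rules(frequent, config, transactions.n)


_RANK_KEYS = {"support", "lift", "confidence"}


def rank_rules(ruleset: RuleSet, key: str = "support", k: int | None = None) -> list[AssociationRule]:
    """Top-k rules by a metric with deterministic tie-breaking.

    Secondary ordering: descending support, descending lift, then
    lexicographic antecedent and consequent.
    """
    if key not in _RANK_KEYS:
        raise ComorbnetError(f"unknown ranking key {key!r}; use one of {sorted(_RANK_KEYS)}")
    if k is not None and k < 1:
        raise ComorbnetError(f"k must be >= 1, got {k}")
    ordered = sorted(
        ruleset.rules,
        key=lambda r: (
            -getattr(r, key),
            -r.support,
            -r.lift,
            r.antecedent,
            r.consequent,
        ),
    )
    return ordered if k is None else ordered[:k]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed rule tables."""
    if math.isinf(x):
        return x
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def itemsets_to_frame(frequent: Iterable[FrequentItemset], min_len: int = 1) -> pd.DataFrame:
    """Frequent itemsets as a table (items joined by ``+``)."""
    rows = [
        {
            "items": "+".join(fi.items),
            "support": fi.support,
            "count": fi.count,
            "length": len(fi.items),
        }
        for fi in frequent
        if len(fi.items) >= min_len
    ]
    return pd.DataFrame(rows, columns=["items", "support", "count", "length"])


def rules_to_frame(rules: Iterable[AssociationRule]) -> pd.DataFrame:
    """Rules as a table mirroring the printed column order; conviction inf -> ``inf``."""
    rows = [
        {
            "antecedent": "+".join(r.antecedent),
            "consequent": "+".join(r.consequent),
            "support_by_antecedent": r.support_antecedent,
            "support_by_consequent": r.support_consequent,
            "support": r.support,
            "confidence": r.confidence,
            "lift": r.lift,
            "leverage": r.leverage,
            "conviction": r.conviction,
        }
        for r in rules
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "antecedent",
            "consequent",
            "support_by_antecedent",
            "support_by_consequent",
            "support",
            "confidence",
            "lift",
            "leverage",
            "conviction",
        ],
    )
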