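"""Shared fixtures: toy transaction sets, random instances, a small study cohort."""

from __future__ import annotations

import numpy as np
import pytest

from comorbnet import cohort_synth
from comorbnet.ehr_coding import TransactionSet


def make_transactions(sets) -> TransactionSet:
    """Build a TransactionSet from an iterable of item collections."""
    txns = tuple((f"t{i}", frozenset(s)) for i, s in enumerate(sets))
    universe = tuple(sorted(frozenset().union(*(s for _tid, s in txns)))) if txns else ()
    return TransactionSet(transactions=txns, universe=universe, n=len(txns))


def random_transactions(rng: np.random.Generator, max_txn=30, max_items=8) -> TransactionSet:
    """A random small transaction set for oracle-equivalence checks."""
    n_items = int(rng.integers(2, max_items + 1))
    n_txn = int(rng.integers(1, max_txn + 1))
    items = [chr(ord("A") + i) for i in range(n_items)]
    sets = []
    for _ in range(n_txn):
        p = rng.uniform(0.2, 0.6)
        sets.append({it for it in items if rng.random() < p})
    return make_transactions(sets)


@pytest.fixture
def toy_transactions() -> TransactionSet:
    """The 4-transaction lattice example: {A,B,C},{A,B},{A,C},{B,C}."""
    return make_transactions([{"A", "B", "C"}, {"A", "B"}, {"A", "C"}, {"B", "C"}])


@pytest.fixture(scope="session")
def study_cohort_csv(tmp_path_factory):
    """A scaled-down synthetic study cohort written as a diagnosis CSV."""
    path = tmp_path_factory.mktemp("cohort") / "cohort.csv"
    spec = cohort_synth.study_spec(n_patients=1200, seed=11)
    cohort_synth.write_cohort_csv(spec, path)
    return path
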