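"""Noisy-OR cohort generator: closed forms, determinism, convergence, skew."""

import numpy as np
import pytest

from comorbnet import cohort_synth
from comorbnet.cohort_synth import (
    ComorbidityBlock,
    SyntheticCohortSpec,
    expected_support,
    generate_cohort,
    planted_truth,
    study_spec,
)
from comorbnet.errors import SpecError


def two_item_spec(n=10_000, seed=42):
    """Two independent items at p = 0.5, no blocks."""
    return SyntheticCohortSpec(
        n_patients=n, background_prevalence={"X01": 0.5, "Y01": 0.5}, seed=seed
    )


def one_block_spec(n=10_000, seed=42, pi=0.5, q=1.0, background=0.0):
    return SyntheticCohortSpec(
        n_patients=n,
        background_prevalence={"X01": background, "Y01": background},
        blocks=(
            ComorbidityBlock("b", pi, {"X01": q, "Y01": q}),
        ),
        seed=seed,
    )


def empirical(records, items):
    items = frozenset(items)
    return sum(1 for r in records if items <= r.categories) / len(records)


class TestExpectedSupport:
    def test_independent_pair_is_product(self):
        spec = SyntheticCohortSpec(
            n_patients=10, background_prevalence={"X01": 0.3, "Y01": 0.4}
        )
        assert expected_support(spec, ["X01", "Y01"]) == pytest.approx(0.12)

    def test_singleton_identity(self):
        spec = SyntheticCohortSpec(n_patients=10, background_prevalence={"X01": 0.3})
        assert expected_support(spec, ["X01"]) == pytest.approx(0.3)

    def test_deterministic_block_pair(self):
        # pi=0.5, q=1, background 0: both items iff the block fires -> 0.5
        assert expected_support(one_block_spec(), ["X01", "Y01"]) == pytest.approx(0.5)

    def test_single_block_closed_form(self):
        # P(i^j) = pi [1-(1-p)(1-q)]^2 + (1-pi) p^2
        spec = one_block_spec(pi=0.4, q=0.9, background=0.1)
        on = 1 - (1 - 0.1) * (1 - 0.9)
        assert expected_support(spec, ["X01", "Y01"]) == pytest.approx(
            0.4 * on**2 + 0.6 * 0.01
        )

    def test_unknown_item_rejected(self):
        with pytest.raises(SpecError, match="not in the category universe"):
            expected_support(two_item_spec(), ["Z99"])

    def test_size_three_rejected(self):
        spec = SyntheticCohortSpec(
            n_patients=10, background_prevalence={"A01": 0.1, "B01": 0.1, "C01": 0.1}
        )
        with pytest.raises(SpecError):
            expected_support(spec, ["A01", "B01", "C01"])


class TestPlantedTruth:
    def test_no_blocks_has_no_positive_pairs(self):
        assert planted_truth(two_item_spec()).positive_pairs == frozenset()

    def test_deterministic_block_pair_is_positive(self):
        truth = planted_truth(one_block_spec())
        assert truth.positive_pairs == {frozenset({"X01", "Y01"})}

    def test_marginals_cover_full_universe(self):
        spec = study_spec(n_patients=10)
        truth = planted_truth(spec)
        assert set(truth.marginal_supports) == set(spec.universe)
        assert all(0 <= p <= 1 for p in truth.marginal_supports.values())
        assert truth.positive_pairs <= set(truth.pair_supports)


class TestGenerateCohort:
    def test_patient_count_and_reproducibility(self):
        spec = one_block_spec(n=200)
        first = generate_cohort(spec)
        second = generate_cohort(spec)
        assert len(first) == 200
        assert first == second

    def test_csv_output_byte_identical(self, tmp_path):
        spec = study_spec(n_patients=150, seed=5)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        cohort_synth.write_cohort_csv(spec, a)
        cohort_synth.write_cohort_csv(spec, b)
        assert a.read_bytes() == b.read_bytes()

    def test_independence_limit_lift_near_one(self):
        records = generate_cohort(two_item_spec())
        p_x = empirical(records, ["X01"])
        p_y = empirical(records, ["Y01"])
        lift = empirical(records, ["X01", "Y01"]) / (p_x * p_y)
        assert lift == pytest.approx(1.0, abs=0.1)

    def test_deterministic_block_empirics(self):
        records = generate_cohort(one_block_spec())
        assert empirical(records, ["X01"]) == pytest.approx(0.5, abs=0.02)
        joint = empirical(records, ["X01", "Y01"])
        assert joint == pytest.approx(0.5, abs=0.02)
        lift = joint / (empirical(records, ["X01"]) * empirical(records, ["Y01"]))
        assert lift == pytest.approx(2.0, abs=0.1)

    def test_invalid_probability_names_field(self):
        with pytest.raises(SpecError, match="membership_prob"):
            ComorbidityBlock("b", 1.5, {"X01": 0.5})
        with pytest.raises(SpecError, match="background_prevalence\\[X01\\]"):
            SyntheticCohortSpec(n_patients=5, background_prevalence={"X01": -0.1})

    def test_block_item_outside_universe_rejected(self):
        with pytest.raises(SpecError, match="not in category universe"):
            SyntheticCohortSpec(
                n_patients=5,
                background_prevalence={"X01": 0.5},
                blocks=(ComorbidityBlock("b", 0.5, {"Z99": 0.5}),),
            )

    def test_period_weights_must_sum_to_one(self):
        with pytest.raises(SpecError, match="sum to 1"):
            SyntheticCohortSpec(
                n_patients=5,
                background_prevalence={"X01": 0.5},
                period_weights={"2019": 0.5, "2020": 0.4},
            )


class TestConvergence:
    """Empirical supports approach closed-form expectations at n = 10,000."""

    def test_planted_singletons_and_pairs_within_002(self):
        spec = SyntheticCohortSpec(
            n_patients=10_000,
            background_prevalence={"A01": 0.2, "B01": 0.3, "C01": 0.15, "D01": 0.05},
            blocks=(
                ComorbidityBlock("b1", 0.4, {"A01": 0.8, "B01": 0.6}),
                ComorbidityBlock("b2", 0.3, {"B01": 0.5, "C01": 0.7}),
            ),
            seed=101,
        )
        records = generate_cohort(spec)
        truth = planted_truth(spec)
        for item, exp in truth.marginal_supports.items():
            assert empirical(records, [item]) == pytest.approx(exp, abs=0.02)
        for pair, exp in truth.pair_supports.items():
            assert empirical(records, pair) == pytest.approx(exp, abs=0.02)
        for pair in truth.positive_pairs:
            i, j = sorted(pair)
            lift = empirical(records, pair) / (
                empirical(records, [i]) * empirical(records, [j])
            )
            assert lift > 1.0


def test_study_cohort_counts_right_skewed():
    """The default study cohort has median ~9 comorbidities, quartiles ~7/12-13."""
    records = generate_cohort(study_spec(n_patients=3000, seed=1))
    counts = np.array([len(r.categories) for r in records])
    assert np.median(counts) == pytest.approx(9, abs=1)
    assert np.percentile(counts, 25) == pytest.approx(7, abs=1)
    assert 11 <= np.percentile(counts, 75) <= 14
    mean, med = counts.mean(), np.median(counts)
    assert mean > med  # right skew
    assert (counts >= 2).mean() > 0.98


def test_admission_years_follow_period_mixture():
    spec = study_spec(n_patients=2000, seed=3)
    records = generate_cohort(spec)
    first_years = np.array([min(y for y, _ in r.admissions) for r in records])
    assert set(first_years) <= set(range(2019, 2025))
    # most-weighted years should dominate the least-weighted
    assert (first_years == 2021).sum() > (first_years == 2024).sum()


def test_spec_yaml_round_trip(tmp_path):
    import yaml

    spec = one_block_spec(n=50, pi=0.4, q=0.9, background=0.1)
    raw = {
        "n_patients": spec.n_patients,
        "background_prevalence": dict(spec.background_prevalence),
        "blocks": [
            {
                "block_id": b.block_id,
                "membership_prob": b.membership_prob,
                "item_probs": dict(b.item_probs),
            }
            for b in spec.blocks
        ],
        "period_weights": dict(spec.period_weights),
        "seed": spec.seed,
    }
    path = tmp_path / "spec.yaml"
    path.write_text(yaml.safe_dump(raw))
    loaded = cohort_synth.spec_from_yaml(path)
    assert generate_cohort(loaded) == generate_cohort(spec)
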