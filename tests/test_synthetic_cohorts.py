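"""The cohort generator and its analytic latent-mixture oracle."""

import json
import math

import numpy as np
import pytest

from fedfpm.dataset import read_cohort, write_cohort
from fedfpm.synthetic_cohorts import (
    DEFAULT_CONDITIONS,
    MORTALITY_ITEM,
    UP_ITEMS,
    CohortProfile,
    ExclusiveGroup,
    LatentCluster,
    LogisticOutcome,
    analytic_itemset_probability,
    analytic_rule,
    main_pool,
    mortality_pool,
    planted_rules,
    pooled_itemset_probability,
    simulate_cohort,
    study_like_profiles,
    toy_fixture,
    up_pool,
)


def _simple_profile(**overrides) -> CohortProfile:
    base = dict(
        agent_id="t",
        n_patients=10,
        item_catalog=("A", "B"),
        baseline_prevalence={"A": 1.0, "B": 0.0},
        seed=1,
    )
    base.update(overrides)
    return CohortProfile(**base)


def test_degenerate_probabilities_give_deterministic_transactions():
    ds = simulate_cohort(_simple_profile())
    assert ds.transactions == [("A",)] * 10


def test_binomial_marginal_calibration():
    profile = _simple_profile(
        n_patients=100_000, baseline_prevalence={"A": 0.3, "B": 0.0}, seed=77
    )
    ds = simulate_cohort(profile)
    freq = sum(1 for t in ds.transactions if "A" in t) / ds.n
    se = math.sqrt(0.3 * 0.7 / ds.n)
    assert abs(freq - 0.3) <= 3 * se


def test_same_seed_reproduces_byte_identical_data():
    p = study_like_profiles(seed=5)[0]
    assert simulate_cohort(p).transactions == simulate_cohort(p).transactions
    p2 = study_like_profiles(seed=6)[0]
    assert simulate_cohort(p).transactions != simulate_cohort(p2).transactions


def test_duplicate_catalog_rejected():
    with pytest.raises(ValueError):
        _simple_profile(item_catalog=("A", "A"))


def test_mortality_item_requires_model():
    with pytest.raises(ValueError):
        _simple_profile(item_catalog=("A", "B", MORTALITY_ITEM))


def test_cluster_lift_raises_co_occurrence():
    profile = _simple_profile(
        n_patients=30_000,
        baseline_prevalence={"A": 0.2, "B": 0.2},
        clusters=[LatentCluster("block", 0.5, {"A": 3.0, "B": 3.0})],
        seed=3,
    )
    ds = simulate_cohort(profile)
    p_joint = sum(1 for t in ds.transactions if t == ("A", "B")) / ds.n
    analytic = analytic_itemset_probability(profile, ("A", "B"))
    # analytic: 0.5*0.36 + 0.5*0.04 = 0.20, well above independence 0.16
    assert analytic == pytest.approx(0.20)
    assert abs(p_joint - analytic) <= 4 * math.sqrt(analytic * (1 - analytic) / ds.n)


def test_exclusive_groups_emit_exactly_one_item():
    profile = _simple_profile(
        item_catalog=("A", "F", "M"),
        baseline_prevalence={"A": 0.5},
        exclusive_groups=[ExclusiveGroup("gender", ("F", "M"), (0.6, 0.4))],
        n_patients=500,
        seed=9,
    )
    for t in simulate_cohort(profile).transactions:
        assert ("F" in t) != ("M" in t)


def test_logistic_outcome_monotone_in_risk_items():
    profile = _simple_profile(
        item_catalog=("A", MORTALITY_ITEM),
        baseline_prevalence={"A": 0.5},
        mortality_model=LogisticOutcome(intercept=-2.0, coefficients={"A": 2.0}),
        n_patients=40_000,
        seed=4,
    )
    ds = simulate_cohort(profile)
    with_a = [t for t in ds.transactions if "A" in t]
    without_a = [t for t in ds.transactions if "A" not in t]
    death = lambda ts: sum(1 for t in ts if MORTALITY_ITEM in t) / len(ts)
    assert death(with_a) == pytest.approx(0.5, abs=0.02)      # sigmoid(0)
    assert death(without_a) == pytest.approx(0.119, abs=0.02)  # sigmoid(-2)
    # and the analytic oracle integrates the same model
    assert analytic_itemset_probability(profile, (MORTALITY_ITEM,)) == pytest.approx(
        0.5 * 0.5 + 0.5 * (1 / (1 + math.exp(2))), rel=1e-12
    )


# -- study-like profiles ---------------------------------------------------

def test_study_sizes_match_descriptives_table(study_profiles):
    assert [p.n_patients for p in study_profiles] == [244, 331, 861, 3786, 5812]
    assert sum(p.n_patients for p in study_profiles) == 11_034


def test_exactly_two_cohorts_record_mortality(study_profiles):
    assert sum(p.mortality_model is not None for p in study_profiles) == 2
    assert {p.agent_id for p in mortality_pool(study_profiles)} == {
        "IACS-like", "SAS-like",
    }


def test_survey_cohort_schema_is_disjoint_on_disease_items(study_profiles):
    (up,) = up_pool(study_profiles)
    assert set(up.item_catalog) & set(DEFAULT_CONDITIONS) == set()
    assert set(UP_ITEMS) <= set(up.item_catalog)


def test_main_catalog_has_47_conditions(study_profiles):
    main = main_pool(study_profiles)[0]
    assert len(set(main.item_catalog) & set(DEFAULT_CONDITIONS)) == 47


def test_planted_structure_includes_strong_rule(study_profiles):
    """By construction at least one planted rule exceeds confidence 0.8
    and lift 1.5 in the main pool."""
    rules = planted_rules(main_pool(study_profiles), 0.2, 0.6, 1.3)
    assert rules
    assert any(r.confidence > 0.8 and r.lift > 1.5 for r in rules)


def test_marginals_match_analytic_for_study_cohort(study_profiles, study_data):
    profile = study_profiles[3]  # IACS-like, n=3786
    ds = study_data[profile.agent_id]
    for item in ("Heart failure", "Hypertension", "Gender female", MORTALITY_ITEM):
        p = analytic_itemset_probability(profile, (item,))
        obs = sum(1 for t in ds.transactions if item in t) / ds.n
        assert abs(obs - p) <= 4 * math.sqrt(p * (1 - p) / ds.n)


def test_analytic_rule_consistency(study_profiles):
    pool = main_pool(study_profiles)
    r = analytic_rule(pool, ("Heart failure",), ("Atrial fibrillation",))
    assert r.support <= r.confidence  # joint <= conditional
    assert r.lift == pytest.approx(
        r.confidence / pooled_itemset_probability(pool, ("Atrial fibrillation",))
    )


# -- fixtures and IO -------------------------------------------------------

def test_toy_fixture_reproduces_worked_numbers(toy):
    assert toy.n == 10
    assert sum(1 for t in toy.transactions if "X" in t) == 5
    assert sum(1 for t in toy.transactions if {"X", "Y"} <= set(t)) == 3
    assert all(t for t in toy.transactions)  # no empty records


def test_profile_json_roundtrip(tmp_path, study_profiles):
    p = study_profiles[3]
    path = p.write(tmp_path / "profile.json")
    loaded = CohortProfile.read(path)
    assert loaded.to_dict() == p.to_dict()
    assert json.loads(path.read_text())["n_patients"] == 3786


def test_cohort_csv_roundtrip(tmp_path, toy):
    csv_path, meta_path = write_cohort(toy, tmp_path, seed=42)
    again = read_cohort(csv_path)
    assert again.transactions == toy.transactions
    assert again.items == toy.items
    meta = json.loads(meta_path.read_text())
    assert meta["n"] == 10 and meta["seed"] == 42
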