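"""The two-step manager/agent protocol: counts only, exact aggregation."""

from fractions import Fraction

import numpy as np
import pytest

from fedfpm.dataset import TransactionDataset, pool, split_dataset
from fedfpm.federation import (
    AgentMessage,
    AuditLog,
    GlobalItemset,
    MiningConfig,
    run_mining,
    step1_local_counts,
    step1_merge,
    step2_aggregate,
    step2_local_rules,
)
from fedfpm.oracle import brute_force_rules
from fedfpm.synthetic_cohorts import toy_fixture


def _rule_key(rules):
    return [
        (r.antecedent, r.consequent, r.support_count, r.antecedent_count,
         r.consequent_count, r.n_total)
        for r in rules
    ]


# -- configuration ---------------------------------------------------------

def test_default_thresholds_are_study_defaults():
    cfg = MiningConfig()
    assert cfg.min_support == Fraction(3, 10)
    assert cfg.min_confidence == Fraction(4, 5)


def test_float_thresholds_stored_as_decimal_rationals():
    cfg = MiningConfig(min_support=0.3, min_confidence=0.8)
    assert cfg.min_support == Fraction(3, 10)
    assert cfg.min_confidence == Fraction(4, 5)


def test_config_validation():
    with pytest.raises(ValueError):
        MiningConfig(min_support=1.5)
    with pytest.raises(ValueError):
        MiningConfig(min_confidence=-0.1)
    with pytest.raises(ValueError):
        MiningConfig(consequent_size=0)


def test_config_file_roundtrip(tmp_path):
    path = tmp_path / "model.yaml"
    path.write_text("min_support: 0.2\nmin_confidence: 0.5\noutcome_item: Mortality\n")
    cfg = MiningConfig.from_file(path)
    assert cfg.min_support == Fraction(1, 5)
    assert cfg.min_confidence == Fraction(1, 2)
    assert cfg.outcome_item == "Mortality"


# -- step 1 ----------------------------------------------------------------

def test_step1_counts_on_toy_fixture(toy):
    msg = step1_local_counts(toy)
    assert msg.itemset_counts[("X",)] == 5
    assert msg.n_local == 10


def test_step1_counts_match_direct_counting(toy):
    msg = step1_local_counts(toy)
    for (item,), count in msg.itemset_counts.items():
        assert count == sum(1 for t in toy.transactions if item in t)


def test_step1_empty_agent_reports_zero_counts():
    empty = TransactionDataset("empty", ("A", "B"), [])
    msg = step1_local_counts(empty)
    assert msg.n_local == 0
    assert dict(msg.itemset_counts) == {("A",): 0, ("B",): 0}


def test_step1_counts_are_partition_invariant(toy):
    rng = np.random.default_rng(5)
    parts = split_dataset(toy, 2, rng)
    merged = step1_merge([step1_local_counts(p) for p in parts], MiningConfig(min_support=0))
    whole = step1_merge([step1_local_counts(toy)], MiningConfig(min_support=0))
    assert dict(merged.global_counts) == dict(whole.global_counts)
    assert merged.n_total == whole.n_total == 10


def test_step1_merge_retention_is_inclusive_at_boundary(toy):
    msg = step1_local_counts(toy)
    kept = step1_merge([msg], MiningConfig(min_support=0.5)).global_counts
    assert ("X",) in kept  # support exactly 0.5 survives
    kept_strict = step1_merge([msg], MiningConfig(min_support=0.500001)).global_counts
    assert ("X",) not in kept_strict


def test_step1_merge_with_default_support_keeps_toy_item(toy):
    kept = step1_merge([step1_local_counts(toy)], MiningConfig(min_support=0.3))
    assert ("X",) in kept.global_counts  # 0.5 >= default 0.3


def test_step1_merge_zero_support_retains_everything(toy):
    kept = step1_merge([step1_local_counts(toy)], MiningConfig(min_support=0))
    assert set(kept.global_counts) == {("X",), ("Y",), ("Z",)}


def test_step1_merge_rejects_empty_message_list():
    with pytest.raises(ValueError):
        step1_merge([], MiningConfig())


# -- step 2 ----------------------------------------------------------------

def test_step2_candidates_include_worked_example_counts(toy):
    cfg = MiningConfig(min_support=0.3, min_confidence=0.5)
    bcast = step1_merge([step1_local_counts(toy)], cfg)
    msg = step2_local_rules(toy, bcast, cfg)
    assert msg.itemset_counts[("X",)] == 5
    assert msg.itemset_counts[("X", "Y")] == 3


def test_step2_on_disjoint_schema_returns_empty_counts(toy):
    cfg = MiningConfig(min_support=0.1, min_confidence=0.5)
    bcast = step1_merge([step1_local_counts(toy)], cfg)
    other = TransactionDataset("survey", ("P", "Q"), [("P",), ("P", "Q")])
    msg = step2_local_rules(other, bcast, cfg)
    assert dict(msg.itemset_counts) == {}


def test_step2_exact_counts_are_partition_invariant(toy):
    cfg = MiningConfig(min_support=0.2, min_confidence=0.5)
    bcast = GlobalItemset(
        itemsets=(("X",), ("Y",), ("X", "Y")), global_counts={}, n_total=10,
        kind="candidates",
    )
    whole = step2_local_rules(toy, bcast, cfg).itemset_counts
    rng = np.random.default_rng(3)
    parts = split_dataset(toy, 3, rng)
    summed = {}
    for p in parts:
        for s, c in step2_local_rules(p, bcast, cfg).itemset_counts.items():
            summed[s] = summed.get(s, 0) + c
    assert summed == dict(whole)


def test_aggregate_reproduces_worked_confidence(toy):
    cfg = MiningConfig(min_support=0.3, min_confidence=0.5)
    bcast = GlobalItemset(
        itemsets=(("X",), ("Y",), ("X", "Y")), global_counts={}, n_total=10,
        kind="candidates",
    )
    msgs = [step2_local_rules(toy, bcast, cfg)]
    rules = {(r.antecedent, r.consequent): r for r in step2_aggregate(msgs, bcast, cfg)}
    assert rules[(("X",), ("Y",))].confidence == Fraction(3, 5)


def test_aggregate_with_zero_thresholds_keeps_every_candidate(toy):
    cfg = MiningConfig(min_support=0, min_confidence=0)
    bcast = GlobalItemset(
        itemsets=(("X",), ("Y",), ("X", "Y")), global_counts={}, n_total=10,
        kind="candidates",
    )
    msgs = [step2_local_rules(toy, bcast, cfg)]
    rules = step2_aggregate(msgs, bcast, cfg)
    assert {(r.antecedent, r.consequent) for r in rules} == {
        (("X",), ("Y",)),
        (("Y",), ("X",)),
    }


def test_aggregate_drops_zero_count_antecedents():
    cfg = MiningConfig(min_support=0, min_confidence=0)
    bcast = GlobalItemset(
        itemsets=(("A",), ("B",), ("A", "B")), global_counts={}, n_total=4,
        kind="candidates",
    )
    msg = AgentMessage("a", 4, {("A",): 0, ("B",): 2, ("A", "B"): 0})
    rules = step2_aggregate([msg], bcast, cfg)
    assert all(r.antecedent != ("A",) for r in rules)


# -- end to end ------------------------------------------------------------

def test_single_agent_equals_centralized(toy):
    for cfg in (
        MiningConfig(min_support=0.3, min_confidence=0.5),
        MiningConfig(min_support=0.1, min_confidence=0.0),
        MiningConfig(min_support=0.0, min_confidence=0.8),
    ):
        assert _rule_key(run_mining([toy], cfg)) == _rule_key(
            brute_force_rules(toy.transactions, cfg)
        )


def test_federated_equals_centralized_on_random_partitions(random_dataset_factory):
    rng = np.random.default_rng(123)
    for _ in range(60):
        ds = random_dataset_factory(rng)
        cfg = MiningConfig(
            min_support=float(rng.choice([0.0, 0.1, 0.25, 0.4])),
            min_confidence=float(rng.choice([0.0, 0.4, 0.7, 1.0])),
        )
        parts = split_dataset(ds, int(rng.integers(1, 6)), rng)
        assert _rule_key(run_mining(parts, cfg)) == _rule_key(
            brute_force_rules(ds.transactions, cfg)
        )


def test_outcome_restricts_pool_and_consequents():
    carrier = TransactionDataset(
        "c", ("A", "Death"), [("A", "Death"), ("A", "Death"), ("A",), ("Death",)]
    )
    bystander = TransactionDataset("b", ("A",), [("A",)] * 4)
    cfg = MiningConfig(min_support=0.25, min_confidence=0.5, outcome_item="Death")
    rules = run_mining([carrier, bystander], cfg)
    assert rules and all(r.consequent == ("Death",) for r in rules)
    # pooled denominator covers only the outcome-carrying agent
    assert all(r.n_total == 4 for r in rules)


def test_outcome_without_carrier_is_an_error():
    ds = TransactionDataset("a", ("A",), [("A",)])
    with pytest.raises(ValueError):
        run_mining([ds], MiningConfig(outcome_item="Death"))


def test_exclude_items_removes_them_from_mining(toy):
    cfg = MiningConfig(min_support=0.1, min_confidence=0.0, exclude_items=("Z",))
    rules = run_mining([toy], cfg)
    assert rules
    assert all("Z" not in r.items for r in rules)


def test_threshold_monotonicity_rules_only_shrink(random_dataset_factory):
    rng = np.random.default_rng(9)
    for _ in range(25):
        ds = random_dataset_factory(rng)
        loose = run_mining([ds], MiningConfig(min_support=0.1, min_confidence=0.3))
        tight = run_mining([ds], MiningConfig(min_support=0.3, min_confidence=0.6))
        assert set(_rule_key(tight)) <= set(_rule_key(loose))


# -- privacy contract ------------------------------------------------------

def test_agent_message_cannot_carry_records():
    with pytest.raises(TypeError):
        AgentMessage("a", 2, {("A",): [("A", "B")]})  # a transaction list
    with pytest.raises(TypeError):
        AgentMessage("a", 2, {(("A", "B"),): 1})  # nested structure as key
    with pytest.raises(ValueError):
        AgentMessage("a", 2, {("A",): 3})  # count exceeding n_local
    msg = AgentMessage("a", 2, {("A",): 1})
    with pytest.raises(TypeError):
        msg.itemset_counts[("B",)] = 1  # payload is immutable


def test_audit_log_contains_only_aggregate_payloads(toy, tmp_path):
    audit = AuditLog()
    run_mining([toy], MiningConfig(min_support=0.2, min_confidence=0.5), audit)
    assert audit.records
    for rec in audit.records:
        payload = rec["payload"]
        assert set(payload) <= {
            "agent_id", "n_local", "itemset_counts",
            "kind", "n_total", "itemsets", "global_counts",
        }
        for value in payload.get("itemset_counts", {}).values():
            assert isinstance(value, int)
    path = audit.write(tmp_path / "audit.jsonl")
    assert path.read_text().count("\n") == len(audit.records)
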