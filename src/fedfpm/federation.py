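"""Manager/agent protocol for privacy-preserving federated rule mining.

Agents hold patient-level transaction data; the manager sees only
aggregate counts. Mining proceeds in two aggregation rounds:

* **Step 1** — every agent reports its single-item counts (computed on an
  FP-tree over its own data) and its local dataset size. The manager sums
  the counts, forms global single-item supports, and prunes items below
  the minimum support.
* **Step 2** — the manager broadcasts the retained items; each agent mines
  its own (item-restricted) data for locally frequent itemsets and reports
  their counts. The manager takes the union of those candidates,
  broadcasts it back, and each agent returns its exact count for every
  candidate in its schema. The manager sums, re-applies the support
  threshold globally, forms candidate rules, computes global confidence
  and lift, and prunes by minimum confidence.

The intermediate candidate exchange is what makes the protocol *exactly*
equivalent to centralized mining of the pooled data: a globally frequent
itemset is locally frequent at at least one agent (its global support is
a size-weighted average of local supports), so the candidate union covers
the global answer, and the final counting pass replaces each agent's
locally pruned counts with exact ones. Every message is an
:class:`AgentMessage` carrying only itemset→count maps — no field can
hold a patient record, which is the protocol's testable privacy contract.

The protocol is simulated in-process; agents and manager exchange
messages through an audited channel rather than a network.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import TransactionDataset
from .fptree import build_tree, mine_itemsets
from .rulestats import (
    AssociationRule,
    Itemset,
    canonical,
    exact_fraction,
    sort_rules,
)


@dataclass(frozen=True)
class MiningConfig:
    """Run parameters for one federated mining model.

    ``min_support`` and ``min_confidence`` accept floats, decimal strings
    or Fractions and are stored as exact rationals; both thresholds are
    inclusive (an itemset or rule *at* the threshold survives). Defaults
    follow the study protocol: support 0.3, confidence 0.8.

    ``outcome_item`` restricts the run to agents whose schema contains the
    outcome and to rules whose consequent is exactly that item (the
    mortality model runs on the two agents that record deaths).
    """

    min_support: Fraction = Fraction(3, 10)
    min_confidence: Fraction = Fraction(4, 5)
    max_antecedent_size: int | None = None
    consequent_size: int = 1
    outcome_item: str | None = None
    exclude_items: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "exclude_items", tuple(self.exclude_items))
        object.__setattr__(self, "min_support", exact_fraction(self.min_support))
        object.__setattr__(self, "min_confidence", exact_fraction(self.min_confidence))
        if not 0 <= self.min_support <= 1:
            raise ValueError("min_support must be in [0, 1]")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.consequent_size < 1:
            raise ValueError("consequent_size must be >= 1")
        if self.max_antecedent_size is not None and self.max_antecedent_size < 1:
            raise ValueError("max_antecedent_size must be >= 1 or None")

    @classmethod
    def from_file(cls, path: str | Path) -> "MiningConfig":
        """Load from a YAML or JSON mapping mirroring the field names."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "min_support": str(self.min_support),
            "min_confidence": str(self.min_confidence),
            "max_antecedent_size": self.max_antecedent_size,
            "consequent_size": self.consequent_size,
            "outcome_item": self.outcome_item,
            "exclude_items": list(self.exclude_items),
        }


@dataclass(frozen=True)
class AgentMessage:
    """The only object that crosses the agent→manager boundary.

    By construction it can carry nothing but the agent label, the local
    transaction count and a map from canonical itemsets to non-negative
    integer counts — no field can hold a transaction or a patient record.
    """

    agent_id: str
    n_local: int
    itemset_counts: Mapping[Itemset, int]

    def __post_init__(self):
        if not isinstance(self.agent_id, str):
            raise TypeError("agent_id must be a string")
        if not isinstance(self.n_local, int) or self.n_local < 0:
            raise TypeError("n_local must be a non-negative integer")
        validated: dict[Itemset, int] = {}
        for key, value in dict(self.itemset_counts).items():
            if not (
                isinstance(key, tuple)
                and key
                and all(isinstance(i, str) for i in key)
                and key == canonical(key)
            ):
                raise TypeError(
                    f"itemset key {key!r} is not a canonical tuple of item labels"
                )
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"count for {key!r} must be an integer")
            value = int(value)
            if not 0 <= value <= self.n_local:
                raise ValueError(
                    f"count {value} for {key!r} outside [0, n_local={self.n_local}]"
                )
            validated[key] = value
        object.__setattr__(self, "itemset_counts", MappingProxyType(validated))

    def to_json_dict(self) -> dict:
        return {
            "agent_id": self.agent_id,
            "n_local": self.n_local,
            "itemset_counts": {
                "|".join(k): v for k, v in sorted(self.itemset_counts.items())
            },
        }


@dataclass(frozen=True)
class GlobalItemset:
    """Manager→agent broadcast: retained items (step 1 output) or the
    merged candidate itemsets (intermediate step-2 exchange)."""

    itemsets: tuple[Itemset, ...]
    global_counts: Mapping[Itemset, int]
    n_total: int
    kind: str = "items"  # "items" (singletons) or "candidates"

    def __post_init__(self):
        object.__setattr__(self, "itemsets", tuple(canonical(s) for s in self.itemsets))
        object.__setattr__(
            self, "global_counts", MappingProxyType(dict(self.global_counts))
        )
        if self.kind not in ("items", "candidates"):
            raise ValueError("kind must be 'items' or 'candidates'")

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_total": self.n_total,
            "itemsets": ["|".join(s) for s in self.itemsets],
            "global_counts": {
                "|".join(k): v for k, v in sorted(self.global_counts.items())
            },
        }


class AuditLog:
    """Record of every message exchanged during a run (JSON-lines export).

    Inspecting the log shows that only count aggregates ever crossed the
    agent/manager boundary.
    """

    def __init__(self):
        self.records: list[dict] = []

    def record(self, phase: str, direction: str, payload: AgentMessage | GlobalItemset):
        self.records.append(
            {"phase": phase, "direction": direction, "payload": payload.to_json_dict()}
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")
        return path


def local_min_count(min_support: Fraction, n_local: int) -> int:
    """Smallest count meeting ``min_support`` locally; at least 1."""
    return max(1, math.ceil(min_support * n_local))


def step1_local_counts(dataset: TransactionDataset) -> AgentMessage:
    """Agent side of step 1: single-item counts over the full local catalog.

    Counts come from the FP-tree header table (construction with threshold
     0 counts every item); catalog items absent from the data report 0.
    """
    tree = build_tree(dataset.transactions, 0)
    header = tree.header_counts()
    counts = {(item,): header.get(item, 0) for item in dataset.items}
    return AgentMessage(
        agent_id=dataset.agent_id, n_local=dataset.n, itemset_counts=counts
    )


def step1_merge(messages: Sequence[AgentMessage], config: MiningConfig) -> GlobalItemset:
    """Manager side of step 1: sum item counts, prune below min_support.

    ``n_total`` pools *all* participating agents; an agent whose schema
    lacks an item simply contributes no count for it.
    """
    if not messages:
        raise ValueError("need at least one agent message")
    n_total = sum(m.n_local for m in messages)
    totals: Counter = Counter()
    for m in messages:
        for itemset, count in m.itemset_counts.items():
            totals[itemset] += count
    if n_total == 0:
        retained: dict[Itemset, int] = {}
    else:
        retained = {
            s: c
            for s, c in totals.items()
            if Fraction(c, n_total) >= config.min_support
        }
    ordered = tuple(sorted(retained))
    return GlobalItemset(
        itemsets=ordered, global_counts=retained, n_total=n_total, kind="items"
    )


def _exact_counts(
    dataset: TransactionDataset, itemsets: Sequence[Itemset]
) -> dict[Itemset, int]:
    """Exact per-itemset counts by bitmask scan (itemsets within schema only)."""
    schema = set(dataset.items)
    wanted = [s for s in itemsets if set(s) <= schema]
    if not wanted:
        return {}
    involved = sorted({i for s in wanted for i in s})
    bit = {item: 1 << j for j, item in enumerate(involved)}
    mask_counts: Counter = Counter()
    for t in dataset.transactions:
        m = 0
        for item in t:
            b = bit.get(item)
            if b is not None:
                m |= b
        mask_counts[m] += 1
    out: dict[Itemset, int] = {}
    if len(involved) <= 63 and mask_counts:
        masks = np.fromiter(mask_counts.keys(), dtype=np.uint64, count=len(mask_counts))
        weights = np.fromiter(
            mask_counts.values(), dtype=np.int64, count=len(mask_counts)
        )
        for s in wanted:
            sm = np.uint64(0)
            for item in s:
                sm |= np.uint64(bit[item])
            out[s] = int(weights[(masks & sm) == sm].sum())
    else:  # arbitrary-width fallback
        for s in wanted:
            sm = 0
            for item in s:
                sm |= bit[item]
            out[s] = sum(c for m, c in mask_counts.items() if m & sm == sm)
    return out


def step2_local_rules(
    dataset: TransactionDataset, global_itemset: GlobalItemset, config: MiningConfig
) -> AgentMessage:
    """Agent side of step 2.

    On an ``items`` broadcast, the agent restricts its transactions to the
    globally retained items and mines its own conditional FP-trees for
    locally frequent itemsets, reporting their counts (the candidate
    itemsets from which rule antecedents and consequents are formed). On a
    ``candidates`` broadcast, it returns its exact count for every
    candidate itemset covered by its schema.
    """
    if not global_itemset.itemsets:
        raise ValueError("global itemset is empty")
    if global_itemset.kind == "candidates":
        counts = _exact_counts(dataset, global_itemset.itemsets)
        return AgentMessage(
            agent_id=dataset.agent_id, n_local=dataset.n, itemset_counts=counts
        )
    allowed = {s[0] for s in global_itemset.itemsets if len(s) == 1}
    restricted = [
        tuple(i for i in t if i in allowed) for t in dataset.transactions
    ]
    restricted = [t for t in restricted if t]
    counts = {}
    if restricted:
        threshold = local_min_count(config.min_support, dataset.n)
        for f in mine_itemsets(restricted, threshold):
            counts[f.items] = f.count
    return AgentMessage(
        agent_id=dataset.agent_id, n_local=dataset.n, itemset_counts=counts
    )


def step2_aggregate(
    messages: Sequence[AgentMessage],
    global_itemset: GlobalItemset,
    config: MiningConfig,
) -> list[AssociationRule]:
    """Manager side of step 2: sum candidate counts, re-apply the global
    support threshold, form rules and prune by global confidence.

    A candidate antecedent with global count 0 cannot support a frequent
    rule and is silently dropped.
    """
    n_total = global_itemset.n_total
    totals: Counter = Counter()
    for m in messages:
        for itemset, count in m.itemset_counts.items():
            totals[itemset] += count
    if n_total == 0:
        return []
    frequent = {
        s: c
        for s, c in totals.items()
        if c >= 1 and Fraction(c, n_total) >= config.min_support
    }
    k = config.consequent_size
    rules: list[AssociationRule] = []
    for s, joint in frequent.items():
        if len(s) <= k:
            continue
        for cons in combinations(s, k):
            consequent = canonical(cons)
            if config.outcome_item is not None and consequent != (config.outcome_item,):
                continue
            antecedent = canonical(set(s) - set(consequent))
            if (
                config.max_antecedent_size is not None
                and len(antecedent) > config.max_antecedent_size
            ):
                continue
            a_count = totals.get(antecedent, 0)
            c_count = totals.get(consequent, 0)
            if a_count == 0:
                continue
            if Fraction(joint, a_count) >= config.min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=consequent,
                        support_count=joint,
                        antecedent_count=a_count,
                        consequent_count=c_count,
                        n_total=n_total,
                    )
                )
    return sort_rules(rules)


def run_mining(
    agents: Sequence[TransactionDataset],
    config: MiningConfig,
    audit: AuditLog | None = None,
) -> list[AssociationRule]:
    """End-to-end federated run: step 1 → merge → step 2 → aggregate.

    With ``config.outcome_item`` set, the agent pool is restricted to the
    agents whose schema contains the outcome, and only rules with the
    outcome as consequent are returned. ``config.exclude_items`` removes
    items from every agent's schema before mining (the multimorbidity
    models exclude the mortality item, which is analyzed in its own run).
    """
    if not agents:
        raise ValueError("need at least one agent")
    pool = list(agents)
    if config.outcome_item is not None:
        pool = [a for a in agents if config.outcome_item in a.items]
        if not pool:
            raise ValueError(
                f"no agent carries outcome item {config.outcome_item!r}"
            )
    if config.exclude_items:
        dropped = set(config.exclude_items)
        if config.outcome_item in dropped:
            raise ValueError("cannot exclude the outcome item")
        pool = [
            TransactionDataset(
                agent_id=a.agent_id,
                items=tuple(i for i in a.items if i not in dropped),
                transactions=[
                    tuple(i for i in t if i not in dropped) for t in a.transactions
                ],
            )
            for a in pool
        ]
    audit = audit if audit is not None else AuditLog()

    msgs1 = [step1_local_counts(a) for a in pool]
    for m in msgs1:
        audit.record("step1", "agent->manager", m)
    global_items = step1_merge(msgs1, config)
    audit.record("step1", "manager->agents", global_items)
    if not global_items.itemsets or global_items.n_total == 0:
        return []

    msgs2 = [step2_local_rules(a, global_items, config) for a in pool]
    for m in msgs2:
        audit.record("step2-candidates", "agent->manager", m)
    candidates = set(global_items.itemsets)
    for m in msgs2:
        candidates.update(m.itemset_counts)
    candidate_bcast = GlobalItemset(
        itemsets=tuple(sorted(candidates)),
        global_counts={},
        n_total=global_items.n_total,
        kind="candidates",
    )
    audit.record("step2-candidates", "manager->agents", candidate_bcast)

    msgs3 = [step2_local_rules(a, candidate_bcast, config) for a in pool]
    for m in msgs3:
        audit.record("step2-counts", "agent->manager", m)
    return step2_aggregate(msgs3, candidate_bcast, config)
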