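"""Naive centralized miner used as an independent cross-check.

Enumerates the powerset of the item universe and counts supporting
transactions by direct scan. Deliberately shares no algorithmic code with
:mod:`fedfpm.fptree` or :mod:`fedfpm.federation`, so agreement between the
two routes is evidence of correctness rather than a tautology. Never used
on the production mining path; the enumeration bound (16 items) keeps it
honest about its purpose.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Iterable

from .fptree import FrequentItemset, Transaction
from .rulestats import (
    AssociationRule,
    Itemset,
    canonical,
    exact_fraction,
    sort_rules,
)

MAX_UNIVERSE = 16


def _prepare(transactions: Iterable[Transaction]) -> tuple[list[frozenset], list[str]]:
    tsets = [frozenset(t) for t in transactions]
    universe = sorted(set().union(*tsets)) if tsets else []
    if len(universe) > MAX_UNIVERSE:
        raise ValueError(
            f"item universe of {len(universe)} exceeds enumeration bound {MAX_UNIVERSE}"
        )
    return tsets, universe

def count_itemset(tsets: list[frozenset], items: Itemset) -> int:
    s = frozenset(items)
    return sum(1 for t in tsets if s <= t)


def brute_force_itemsets(
    transactions: Iterable[Transaction], min_support
) -> list[FrequentItemset]:
    """Every observed itemset whose support meets ``min_support`` (inclusive).

    Support is compared in exact rational arithmetic; an itemset must occur
    at least once to be reported.
    """
    min_support = exact_fraction(min_support)
    tsets, universe = _prepare(transactions)
    n = len(tsets)
    out: list[FrequentItemset] = []
    if n == 0:
        return out
    for size in range(1, len(universe) + 1):
        for combo in combinations(universe, size):
            c = count_itemset(tsets, combo)
            if c >= 1 and Fraction(c, n) >= min_support:
                out.append(FrequentItemset(canonical(combo), c))
    out.sort(key=lambda f: (len(f.items), f.items))
    return out


def brute_force_rules(transactions: Iterable[Transaction], config) -> list[AssociationRule]:
    """All rules A => C passing ``config`` thresholds, by exhaustive split.

    ``config`` is a :class:`fedfpm.federation.MiningConfig` (duck-typed here
    to keep this module import-independent of the protocol code).
    """
    excluded = set(getattr(config, "exclude_items", ()))
    if excluded:
        transactions = [
            tuple(i for i in t if i not in excluded) for t in transactions
        ]
    tsets, _ = _prepare(transactions)
    n = len(tsets)
    frequent = brute_force_itemsets(transactions, config.min_support)
    counts = {f.items: f.count for f in frequent}
    min_conf = exact_fraction(config.min_confidence)
    k = config.consequent_size
    rules: list[AssociationRule] = []
    for f in frequent:
        if len(f.items) <= k:
            continue
        for cons in combinations(f.items, k):
            consequent = canonical(cons)
            if config.outcome_item is not None and consequent != (config.outcome_item,):
                continue
            antecedent = canonical(set(f.items) - set(consequent))
            if (
                config.max_antecedent_size is not None
                and len(antecedent) > config.max_antecedent_size
            ):
                continue
            # subsets of a frequent itemset are frequent, so counts has them
            a_count = counts.get(antecedent)
            c_count = counts.get(consequent)
            if a_count is None:
                a_count = count_itemset(tsets, antecedent)
            if c_count is None:
                c_count = count_itemset(tsets, consequent)
            if a_count == 0:
                continue
            if Fraction(f.count, a_count) >= min_conf:
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=consequent,
                        support_count=f.count,
                        antecedent_count=a_count,
                        consequent_count=c_count,
                        n_total=n,
                    )
                )
    return sort_rules(rules)
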