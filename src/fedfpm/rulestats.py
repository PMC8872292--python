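"""Association-rule statistics: support, confidence and lift.

All three statistics are ratios of transaction counts. They are kept as
exact :class:`fractions.Fraction` values internally so that threshold
comparisons (``support >= min_support``) behave like the decimal
arithmetic a reader does on paper, with no floating-point boundary
artifacts; decimal rendering happens only at report time.

Glossary note: in the epidemiological literature on multimorbidity the
lift is sometimes loosely called a "correlation". It is the ratio
``confidence / P(consequent)`` — a measure of association strength, not
a Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal

#: Canonical in-memory itemset: a sorted, duplicate-free tuple of item labels.
Itemset = tuple[str, ...]


def canonical(items: Iterable[str]) -> Itemset:
    """Return the canonical (sorted, deduplicated) form of an itemset."""
    return tuple(sorted(set(items)))


def exact_fraction(value) -> Fraction:
    """Coerce a threshold to an exact rational.

    Floats are interpreted through their *decimal* literal (``0.3`` means
    3/10, not the nearest binary double), so thresholds written in config
    files compare exactly against count ratios.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise TypeError("boolean is not a valid threshold")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as an exact fraction")


def support(count: int, n_total: int) -> Fraction:
    """Fraction of the ``n_total`` transactions that contain an itemset.

    For a single disease item this is its prevalence.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= count <= n_total:
        raise ValueError(f"count {count} outside [0, {n_total}]")
    return Fraction(count, n_total)


def confidence(joint_count: int, antecedent_count: int) -> Fraction:
    """Conditional frequency P(consequent | antecedent) = count(A∪C)/count(A)."""
    if antecedent_count < 1:
        raise ValueError("antecedent_count must be >= 1")
    if not 0 <= joint_count <= antecedent_count:
        raise ValueError(
            f"joint_count {joint_count} outside [0, {antecedent_count}]"
        )
    return Fraction(joint_count, antecedent_count)


def lift(confidence_value: Fraction, consequent_support: Fraction) -> Fraction:
    """Ratio of rule confidence to the consequent's marginal support.

    Greater than 1 means the antecedent raises the probability of the
    consequent (positive association); below 1 it lowers it.
    """
    consequent_support = exact_fraction(consequent_support)
    if consequent_support <= 0:
        raise ValueError("consequent_support must be > 0")
    return exact_fraction(confidence_value) / consequent_support


@dataclass(frozen=True)
class AssociationRule:
    """One mined rule ``antecedent => consequent`` with its global counts.

    The statistics are derived properties of the stored counts, so the
    consistency chain ``lift * consequent_support == confidence`` and
    ``confidence * antecedent_count == support_count`` holds exactly.
    """

    antecedent: Itemset
    consequent: Itemset
    support_count: int       # count of antecedent ∪ consequent
    antecedent_count: int
    consequent_count: int
    n_total: int

    def __post_init__(self):
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")
        if self.antecedent != canonical(self.antecedent):
            raise ValueError("antecedent not in canonical form")
        if self.consequent != canonical(self.consequent):
            raise ValueError("consequent not in canonical form")
        if not (
            0
            <= self.support_count
            <= min(self.antecedent_count, self.consequent_count)
            <= max(self.antecedent_count, self.consequent_count)
            <= self.n_total
        ):
            raise ValueError("inconsistent rule counts")

    @property
    def support(self) -> Fraction:
        return support(self.support_count, self.n_total)

    @property
    def confidence(self) -> Fraction:
        return confidence(self.support_count, self.antecedent_count)

    @property
    def lift(self) -> Fraction:
        return lift(self.confidence, support(self.consequent_count, self.n_total))

    @property
    def items(self) -> Itemset:
        return canonical(self.antecedent + self.consequent)


def classify_correlation(
    rule: AssociationRule,
) -> Literal["positive", "negative", "independent"]:
    """Classify a rule's association direction from its exact lift."""
    lv = rule.lift
    if lv > 1:
        return "positive"
    if lv < 1:
        return "negative"
    return "independent"


def sort_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Deterministic report order: descending lift, then descending
    confidence, then lexicographic on (antecedent, consequent)."""
    return sorted(
        rules,
        key=lambda r: (-r.lift, -r.confidence, r.antecedent, r.consequent),
    )
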