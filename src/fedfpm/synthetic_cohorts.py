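"""Synthetic multi-cohort generator for federated multimorbidity mining.

Real multi-site EHR cohorts of this kind are not publicly deposited, so
this module generates per-agent transaction datasets with the statistical
structure the analysis assumes: five heterogeneous cohorts of very old,
multimorbid patients; clustered disease co-occurrence (cardiometabolic,
cardiovascular and mental blocks); a six-month mortality outcome recorded
at only two sites; and one site whose variable schema is disjoint from
the others (a frailty survey rather than EHR diagnoses).

Generative model, per patient:

1. draw independent Bernoulli memberships for each latent cluster;
2. each condition item is present independently with probability
   ``clamp(baseline × ∏ lift_factor)`` over the clusters the patient
   belongs to that list the item;
3. mutually exclusive categorical groups (gender, age band) draw one item
   per group from fixed probabilities;
4. if the cohort records mortality, the outcome is Bernoulli with
   logit = intercept + Σ coefficients over the items present.

Conditional independence given cluster membership keeps every itemset
probability available in closed form (enumeration over the small latent
space), so planted association rules have analytically known support,
confidence and lift — the yardstick the mining tests recover against.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataset import TransactionDataset, pool, read_cohort, read_cohort_dir, write_cohort  # noqa: F401 (re-exported)
from .rulestats import Itemset, canonical

MORTALITY_ITEM = "Mortality"

#: Conditions named in the study's result tables...
_NAMED_CONDITIONS = (
    "Atrial fibrillation",
    "Chronic anemia",
    "Chronic kidney disease",
    "Coronary heart disease",
    "Heart failure",
    "Hypertension",
    "Diabetes mellitus",
    "Hyperlipidemia",
    "Obesity",
    "Depression",
    "Anxiety",
)
#: ...padded with generic chronic-condition labels to the 47 analyzed.
_PADDING_CONDITIONS = (
    "COPD",
    "Asthma",
    "Osteoarthritis",
    "Osteoporosis",
    "Rheumatoid arthritis",
    "Dementia",
    "Parkinson disease",
    "Stroke",
    "Epilepsy",
    "Migraine",
    "Cataract",
    "Glaucoma",
    "Hearing loss",
    "Hypothyroidism",
    "Hyperthyroidism",
    "Gout",
    "Chronic liver disease",
    "Peptic ulcer disease",
    "Inflammatory bowel disease",
    "Diverticular disease",
    "Prostate disorders",
    "Urinary incontinence",
    "Chronic back pain",
    "Peripheral artery disease",
    "Venous thromboembolism",
    "Valvular heart disease",
    "Conduction disorders",
    "Chronic sinusitis",
    "Psoriasis",
    "Sleep apnea",
    "Chronic insomnia",
    "Substance use disorder",
    "Schizophrenia",
    "Bipolar disorder",
    "Solid organ cancer",
    "Hematological cancer",
)
DEFAULT_CONDITIONS: tuple[str, ...] = _NAMED_CONDITIONS + _PADDING_CONDITIONS
assert len(DEFAULT_CONDITIONS) == 47

POLYPHARMACY_ITEM = "Polypharmacy"
GENDER_ITEMS = ("Gender female", "Gender male")
AGE_BAND_ITEMS = ("Age 65-70", "Age 70-80", "Age 80 and older")

#: Survey variables of the frailty-app cohort (disjoint from the EHR set).
UP_ITEMS = (
    "Memory complaints",
    "Vision difficulties",
    "Hearing difficulties",
    "Feeling down or depressed lately",
    "Feeling nervous or anxious lately",
    "Unintentional weight loss",
    "Domiciliary care",
)
UP_POLY_ITEM = "Polymedicated"


@dataclass(frozen=True)
class LatentCluster:
    """A latent co-occurrence block: members get each listed item's
    baseline prevalence multiplied by a lift factor (clamped to [0,1])."""

    label: str
    membership_prob: float
    lift_factors: Mapping[str, float]

    def __post_init__(self):
        if not 0 <= self.membership_prob <= 1:
            raise ValueError("membership_prob must be in [0, 1]")
        for item, f in self.lift_factors.items():
            if f < 0:
                raise ValueError(f"lift factor for {item!r} must be >= 0")
        object.__setattr__(self, "lift_factors", dict(self.lift_factors))


@dataclass(frozen=True)
class LogisticOutcome:
    """Logistic model for the mortality item: logit = intercept + Σ
    coefficients over the condition items present in the patient."""

    intercept: float
    coefficients: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "coefficients", dict(self.coefficients))


@dataclass(frozen=True)
class ExclusiveGroup:
    """Mutually exclusive categorical items (e.g. gender, age band); one
    item is drawn per patient. Probabilities must sum to <= 1; any
    remainder means no item from the group."""

    label: str
    items: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "probabilities", tuple(float(p) for p in self.probabilities))
        if len(self.items) != len(self.probabilities):
            raise ValueError("items and probabilities must align")
        if any(p < 0 for p in self.probabilities):
            raise ValueError("group probabilities must be non-negative")
        if sum(self.probabilities) > 1 + 1e-12:
            raise ValueError("group probabilities must sum to <= 1")


@dataclass
class CohortProfile:
    """Generative specification of one synthetic cohort."""

    agent_id: str
    n_patients: int
    item_catalog: tuple[str, ...]
    baseline_prevalence: dict[str, float]
    clusters: list[LatentCluster] = field(default_factory=list)
    exclusive_groups: list[ExclusiveGroup] = field(default_factory=list)
    mortality_model: LogisticOutcome | None = None
    mean_age: float = 82.0
    age_sd: float = 7.0
    prop_women: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.item_catalog = tuple(self.item_catalog)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(set(self.item_catalog)) != len(self.item_catalog):
            raise ValueError("item catalog contains duplicate labels")
        catalog = set(self.item_catalog)
        group_items = {i for g in self.exclusive_groups for i in g.items}
        for item, p in self.baseline_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {item!r} outside [0, 1]")
            if item not in catalog:
                raise ValueError(f"baseline item {item!r} not in catalog")
        if not group_items <= catalog:
            raise ValueError("exclusive-group items must be in the catalog")
        if group_items & set(self.baseline_prevalence):
            raise ValueError("group items cannot also have baseline prevalences")
        for cluster in self.clusters:
            bad = set(cluster.lift_factors) - set(self.baseline_prevalence)
            if bad:
                raise ValueError(
                    f"cluster {cluster.label!r} lifts unknown items {sorted(bad)}"
                )
        if self.mortality_model is None:
            if MORTALITY_ITEM in catalog:
                raise ValueError(
                    "catalog lists the mortality item but no mortality model is set"
                )
        else:
            if MORTALITY_ITEM not in catalog:
                raise ValueError("mortality model set but item not in catalog")
            bad = set(self.mortality_model.coefficients) - set(self.baseline_prevalence)
            if bad:
                raise ValueError(f"mortality coefficients on unknown items {sorted(bad)}")
        covered = set(self.baseline_prevalence) | group_items | {MORTALITY_ITEM}
        uncovered = catalog - covered
        if uncovered:
            raise ValueError(f"catalog items without a generator: {sorted(uncovered)}")
        if not 0 <= self.prop_women <= 1:
            raise ValueError("prop_women must be in [0, 1]")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "agent_id": self.agent_id,
            "n_patients": self.n_patients,
            "item_catalog": list(self.item_catalog),
            "baseline_prevalence": dict(self.baseline_prevalence),
            "clusters": [
                {
                    "label": c.label,
                    "membership_prob": c.membership_prob,
                    "lift_factors": dict(c.lift_factors),
                }
                for c in self.clusters
            ],
            "exclusive_groups": [
                {
                    "label": g.label,
                    "items": list(g.items),
                    "probabilities": list(g.probabilities),
                }
                for g in self.exclusive_groups
            ],
            "mortality_model": (
                None
                if self.mortality_model is None
                else {
                    "intercept": self.mortality_model.intercept,
                    "coefficients": dict(self.mortality_model.coefficients),
                }
            ),
            "mean_age": self.mean_age,
            "age_sd": self.age_sd,
            "prop_women": self.prop_women,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortProfile":
        raw = dict(raw)
        raw["clusters"] = [LatentCluster(**c) for c in raw.get("clusters", [])]
        raw["exclusive_groups"] = [
            ExclusiveGroup(g["label"], tuple(g["items"]), tuple(g["probabilities"]))
            for g in raw.get("exclusive_groups", [])
        ]
        mm = raw.get("mortality_model")
        raw["mortality_model"] = None if mm is None else LogisticOutcome(**mm)
        raw["item_catalog"] = tuple(raw["item_catalog"])
        return cls(**raw)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "CohortProfile":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _item_prob(profile: CohortProfile, item: str, membership: Sequence[bool]) -> float:
    """Presence probability of a baseline item given cluster memberships."""
    p = profile.baseline_prevalence[item]
    for member, cluster in zip(membership, profile.clusters):
        if member:
            p *= cluster.lift_factors.get(item, 1.0)
    return min(1.0, p)


def simulate_cohort(profile: CohortProfile) -> TransactionDataset:
    """Draw one agent's transaction dataset; deterministic given the seed."""
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_patients
    base_items = [i for i in profile.item_catalog if i in profile.baseline_prevalence]

    k = len(profile.clusters)
    membership = np.zeros((n, k), dtype=bool)
    for j, cluster in enumerate(profile.clusters):
        membership[:, j] = rng.random(n) < cluster.membership_prob

    # per-patient presence probability for every baseline item
    probs = np.tile(
        np.array([profile.baseline_prevalence[i] for i in base_items]), (n, 1)
    )
    for j, cluster in enumerate(profile.clusters):
        factors = np.array([cluster.lift_factors.get(i, 1.0) for i in base_items])
        probs[membership[:, j]] *= factors
    np.clip(probs, 0.0, 1.0, out=probs)
    present = rng.random((n, len(base_items))) < probs

    group_choice: dict[str, np.ndarray] = {}
    for g in profile.exclusive_groups:
        cum = np.cumsum(g.probabilities)
        u = rng.random(n)
        group_choice[g.label] = np.searchsorted(cum, u, side="right")  # len(items) = none

    ages = rng.normal(profile.mean_age, profile.age_sd, size=n)

    transactions: list[Itemset] = []
    mortality = None
    if profile.mortality_model is not None:
        mm = profile.mortality_model
        coef = np.array([mm.coefficients.get(i, 0.0) for i in base_items])
        logit = mm.intercept + present @ coef
        p_death = 1.0 / (1.0 + np.exp(-logit))
        mortality = rng.random(n) < p_death

    for i in range(n):
        items = [item for item, on in zip(base_items, present[i]) if on]
        for g in profile.exclusive_groups:
            idx = group_choice[g.label][i]
            if idx < len(g.items):
                items.append(g.items[idx])
        if mortality is not None and mortality[i]:
            items.append(MORTALITY_ITEM)
        transactions.append(canonical(items))

    return TransactionDataset(
        agent_id=profile.agent_id,
        items=canonical(profile.item_catalog),
        transactions=transactions,
        ages=ages,
    )


# ---------------------------------------------------------------------------
# Analytic latent-mixture oracle
# ---------------------------------------------------------------------------

def _membership_space(profile: CohortProfile):
    """All cluster-membership vectors with their probabilities."""
    k = len(profile.clusters)
    for bits in itertools.product((False, True), repeat=k):
        w = 1.0
        for member, cluster in zip(bits, profile.clusters):
            w *= cluster.membership_prob if member else 1 - cluster.membership_prob
        yield bits, w


def _group_factor(profile: CohortProfile, itemset: Iterable[str]) -> float:
    """Probability the exclusive-group draws produce the group items in
    ``itemset``; 0 if the itemset asks for two items of one group."""
    wanted = set(itemset)
    factor = 1.0
    for g in profile.exclusive_groups:
        hits = [i for i in g.items if i in wanted]
        if len(hits) > 1:
            return 0.0
        if hits:
            factor *= g.probabilities[g.items.index(hits[0])]
    return factor


def analytic_itemset_probability(profile: CohortProfile, itemset: Iterable[str]) -> float:
    """Exact P(itemset ⊆ patient) under the profile's generative model.

    Enumerates the latent space: cluster memberships, and — when the
    itemset involves the mortality outcome — the presence pattern of the
    logistic model's coefficient items, whose joint with the outcome does
    not factorize otherwise.
    """
    itemset = canonical(itemset)
    catalog = set(profile.item_catalog)
    if not set(itemset) <= catalog:
        return 0.0
    wants_mortality = MORTALITY_ITEM in itemset
    if wants_mortality and profile.mortality_model is None:
        raise ValueError(f"profile {profile.agent_id!r} has no mortality model")
    base_in = [i for i in itemset if i in profile.baseline_prevalence]
    gfactor = _group_factor(profile, itemset)
    if gfactor == 0.0:
        return 0.0

    total = 0.0
    if not wants_mortality:
        for membership, w in _membership_space(profile):
            p = w
            for item in base_in:
                p *= _item_prob(profile, item, membership)
            total += p
        return total * gfactor

    mm = profile.mortality_model
    coef_items = sorted(mm.coefficients)
    free = [i for i in coef_items if i not in base_in]
    fixed_logit = mm.intercept + sum(mm.coefficients.get(i, 0.0) for i in base_in)
    for membership, w in _membership_space(profile):
        p_states = [_item_prob(profile, i, membership) for i in free]
        p_base = w
        for item in base_in:
            p_base *= _item_prob(profile, item, membership)
        e_sigma = 0.0
        for pattern in itertools.product((0, 1), repeat=len(free)):
            pw = 1.0
            logit = fixed_logit
            for on, item, pi in zip(pattern, free, p_states):
                pw *= pi if on else 1 - pi
                if on:
                    logit += mm.coefficients[item]
            e_sigma += pw / (1.0 + math.exp(-logit))
        total += p_base * e_sigma
    return total * gfactor


def pooled_itemset_probability(
    profiles: Sequence[CohortProfile], itemset: Iterable[str]
) -> float:
    """Size-weighted itemset probability over a pool of cohorts.

    A cohort whose schema lacks some item of the itemset contributes
    probability 0 — exactly how the federated count aggregation treats
    heterogeneous schemas.
    """
    itemset = canonical(itemset)
    n_total = sum(p.n_patients for p in profiles)
    acc = 0.0
    for p in profiles:
        if set(itemset) <= set(p.item_catalog):
            acc += p.n_patients * analytic_itemset_probability(p, itemset)
    return acc / n_total


@dataclass(frozen=True)
class PlantedRule:
    """A rule with analytically known pooled statistics."""

    antecedent: Itemset
    consequent: Itemset
    support: float
    confidence: float
    lift: float


def analytic_rule(
    profiles: Sequence[CohortProfile],
    antecedent: Iterable[str],
    consequent: Iterable[str],
) -> PlantedRule:
    """Pooled analytic support/confidence/lift of a candidate rule."""
    antecedent = canonical(antecedent)
    consequent = canonical(consequent)
    p_joint = pooled_itemset_probability(profiles, antecedent + consequent)
    p_ante = pooled_itemset_probability(profiles, antecedent)
    p_cons = pooled_itemset_probability(profiles, consequent)
    conf = p_joint / p_ante if p_ante > 0 else 0.0
    return PlantedRule(
        antecedent=antecedent,
        consequent=consequent,
        support=p_joint,
        confidence=conf,
        lift=conf / p_cons if p_cons > 0 else 0.0,
    )


CARDIOVASCULAR_ITEMS = (
    "Atrial fibrillation",
    "Chronic anemia",
    "Chronic kidney disease",
    "Coronary heart disease",
    "Heart failure",
)


def planted_rules(
    profiles: Sequence[CohortProfile],
    min_support: float = 0.2,
    min_confidence: float = 0.6,
    min_lift: float = 1.3,
    candidates: Sequence[tuple[Itemset, Itemset]] | None = None,
    support_margin: float = 0.02,
) -> list[PlantedRule]:
    """The rules the generator plants, with their analytic statistics.

    Candidates default to antecedents of up to three cardiovascular-block
    items (plus hypertension/polypharmacy companions where in-schema) and
    single cardiovascular consequents; when every profile records
    mortality, consequents of ``Mortality`` are scanned instead. A
    candidate counts as planted when its analytic confidence and lift
    clear the thresholds and its analytic support clears ``min_support``
    by ``support_margin`` (several sampling standard errors at the study
    size, so recovery is not a coin flip at the threshold).
    """
    schema = set.intersection(*(set(p.item_catalog) for p in profiles))
    if candidates is None:
        all_mortality = all(p.mortality_model is not None for p in profiles)
        cv = [i for i in CARDIOVASCULAR_ITEMS if i in schema]
        companions = [i for i in ("Hypertension", POLYPHARMACY_ITEM) if i in schema]
        up_items = [i for i in UP_ITEMS + (UP_POLY_ITEM,) if i in schema]
        pool_items = cv + companions if cv else up_items
        consequent_pool = (
            [(MORTALITY_ITEM,)] if all_mortality else [(i,) for i in (cv or up_items)]
        )
        candidates = []
        for size in (1, 2, 3):
            for ante in itertools.combinations(pool_items, size):
                for cons in consequent_pool:
                    if cons[0] in ante:
                        continue
                    candidates.append((canonical(ante), canonical(cons)))
    out = []
    for ante, cons in candidates:
        rule = analytic_rule(profiles, ante, cons)
        if (
            rule.support >= min_support + support_margin
            and rule.confidence >= min_confidence
            and rule.lift >= min_lift
        ):
            out.append(rule)
    out.sort(key=lambda r: (-r.lift, -r.confidence, r.antecedent, r.consequent))
    return out


# ---------------------------------------------------------------------------
# Study-like profiles
# ---------------------------------------------------------------------------

def _main_pool_profile(
    agent_id: str,
    n: int,
    mean_age: float,
    prop_women: float,
    age_probs: tuple[float, float, float],
    seed: int,
    cv_membership: float,
    cm_membership: float,
    with_mortality: bool,
) -> CohortProfile:
    baseline = {
        "Hypertension": 0.50,
        "Diabetes mellitus": 0.22,
        "Hyperlipidemia": 0.24,
        "Obesity": 0.16,
        "Heart failure": 0.17,
        "Chronic kidney disease": 0.15,
        "Atrial fibrillation": 0.15,
        "Chronic anemia": 0.15,
        "Coronary heart disease": 0.15,
        "Depression": 0.14,
        "Anxiety": 0.12,
        POLYPHARMACY_ITEM: 0.50,
    }
    for j, cond in enumerate(_PADDING_CONDITIONS):
        baseline[cond] = 0.02 + 0.10 * ((j * 7) % 11) / 10.0  # 0.02..0.12 spread
    clusters = [
        LatentCluster(
            "cardiometabolic",
            cm_membership,
            {
                "Diabetes mellitus": 2.5,
                "Hyperlipidemia": 2.2,
                "Hypertension": 1.5,
                "Obesity": 2.2,
                POLYPHARMACY_ITEM: 1.25,
            },
        ),
        LatentCluster(
            "cardiovascular",
            cv_membership,
            {
                "Heart failure": 5.0,
                "Chronic kidney disease": 5.0,
                "Atrial fibrillation": 5.0,
                "Chronic anemia": 5.0,
                "Coronary heart disease": 5.0,
                "Hypertension": 1.55,
                POLYPHARMACY_ITEM: 1.3,
            },
        ),
        LatentCluster(
            "mental",
            0.28,
            {"Depression": 3.5, "Anxiety": 3.5},
        ),
    ]
    groups = [
        ExclusiveGroup("gender", GENDER_ITEMS, (prop_women, 1 - prop_women)),
        ExclusiveGroup("age_band", AGE_BAND_ITEMS, age_probs),
    ]
    catalog = DEFAULT_CONDITIONS + (POLYPHARMACY_ITEM,) + GENDER_ITEMS + AGE_BAND_ITEMS
    mortality = None
    if with_mortality:
        catalog = catalog + (MORTALITY_ITEM,)
        mortality = LogisticOutcome(
            intercept=-2.8,
            coefficients={
                "Heart failure": 1.8,
                "Chronic kidney disease": 1.6,
                "Chronic anemia": 0.9,
                "Coronary heart disease": 0.9,
                "Diabetes mellitus": 0.6,
            },
        )
    return CohortProfile(
        agent_id=agent_id,
        n_patients=n,
        item_catalog=catalog,
        baseline_prevalence=baseline,
        clusters=clusters,
        exclusive_groups=groups,
        mortality_model=mortality,
        mean_age=mean_age,
        age_sd=6.5,
        prop_women=prop_women,
        seed=seed,
    )


def _up_profile(seed: int) -> CohortProfile:
    baseline = {
        "Memory complaints": 0.20,
        "Vision difficulties": 0.18,
        "Hearing difficulties": 0.18,
        "Feeling down or depressed lately": 0.16,
        "Feeling nervous or anxious lately": 0.16,
        "Unintentional weight loss": 0.10,
        "Domiciliary care": 0.12,
        UP_POLY_ITEM: 0.50,
    }
    clusters = [
        LatentCluster(
            "frailty",
            0.55,
            {
                "Memory complaints": 4.0,
                "Vision difficulties": 4.4,
                "Hearing difficulties": 4.4,
                "Feeling down or depressed lately": 4.0,
                "Feeling nervous or anxious lately": 3.8,
                "Unintentional weight loss": 2.0,
                "Domiciliary care": 2.0,
                UP_POLY_ITEM: 1.8,
            },
        )
    ]
    groups = [
        ExclusiveGroup("gender", GENDER_ITEMS, (0.575, 0.425)),
        ExclusiveGroup("age_band", AGE_BAND_ITEMS, (0.25, 0.45, 0.30)),
    ]
    catalog = UP_ITEMS + (UP_POLY_ITEM,) + GENDER_ITEMS + AGE_BAND_ITEMS
    return CohortProfile(
        agent_id="UP-like",
        n_patients=861,
        item_catalog=catalog,
        baseline_prevalence=baseline,
        clusters=clusters,
        exclusive_groups=groups,
        mortality_model=None,
        mean_age=76.6,
        age_sd=6.0,
        prop_women=0.575,
        seed=seed,
    )


def study_like_profiles(seed: int = 2022) -> list[CohortProfile]:
    """Five cohort profiles mirroring the study's sites.

    Sizes and demographics follow the study's descriptives (n = 244, 331,
    861, 3786, 5812; pooled 11,034). The survey-based cohort (UP-like)
    uses a disjoint item schema; only the two largest cohorts (IACS-like,
    SAS-like) record the six-month mortality outcome. Cluster membership
    varies mildly across sites (the nursing-home cohort is sicker), so
    the pooled data are heterogeneous but the planted associations hold
    pool-wide.
    """
    return [
        _main_pool_profile(
            "UNIGE-like", 244, 81.8, 0.471, (0.10, 0.30, 0.60), seed + 1,
            cv_membership=0.48, cm_membership=0.48, with_mortality=False,
        ),
        _main_pool_profile(
            "UCSC-like", 331, 95.5, 0.716, (0.0, 0.05, 0.95), seed + 2,
            cv_membership=0.58, cm_membership=0.50, with_mortality=False,
        ),
        _up_profile(seed + 3),
        _main_pool_profile(
            "IACS-like", 3786, 82.1, 0.499, (0.12, 0.33, 0.55), seed + 4,
            cv_membership=0.50, cm_membership=0.50, with_mortality=True,
        ),
        _main_pool_profile(
            "SAS-like", 5812, 82.2, 0.494, (0.12, 0.32, 0.56), seed + 5,
            cv_membership=0.50, cm_membership=0.52, with_mortality=True,
        ),
    ]


def main_pool(profiles: Sequence[CohortProfile]) -> list[CohortProfile]:
    """The four EHR-schema cohorts mined together (everything but UP-like)."""
    return [p for p in profiles if "Memory complaints" not in p.item_catalog]


def up_pool(profiles: Sequence[CohortProfile]) -> list[CohortProfile]:
    """The survey-schema cohort, analyzed independently."""
    return [p for p in profiles if "Memory complaints" in p.item_catalog]


def mortality_pool(profiles: Sequence[CohortProfile]) -> list[CohortProfile]:
    """The cohorts that record the six-month mortality outcome."""
    return [p for p in profiles if p.mortality_model is not None]


def toy_fixture() -> TransactionDataset:
    """Ten hand-written transactions reproducing the protocol's worked
    numbers: item X occurs in 5 of 10 records (support 0.5) and {X, Y}
    in 3 (confidence of X => Y is 3/5 = 0.6)."""
    transactions = [
        ("X", "Y"),
        ("X", "Y"),
        ("X", "Y"),
        ("X",),
        ("X", "Z"),
        ("Y",),
        ("Y", "Z"),
        ("Z",),
        ("Z",),
        ("Z",),
    ]
    return TransactionDataset(
        agent_id="toy", items=("X", "Y", "Z"), transactions=list(transactions)
    )
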