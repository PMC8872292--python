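"""Cohort descriptives and rule-report rendering.

Descriptives follow the study-table convention: one row per cohort with
size, share of the pooled population, mean age and percent women, plus a
pooled total row whose mean age and percent women are size-weighted
averages of the cohort values.

Rule reports use the "Antecedent ≥ Consequent" presentation: one row per
rule with the antecedent item list, the consequent, confidence and lift.
CSV output uses the ASCII separator ``=>``; pretty-printed text keeps the
``≥`` glyph. Note that "lift" is occasionally called "correlation" in
this literature; it is confidence divided by consequent support, not a
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .federation import MiningConfig
from .rulestats import AssociationRule, sort_rules

ITEM_SEPARATOR = "; "


@dataclass(frozen=True)
class CohortRow:
    label: str
    n: int
    mean_age: float
    percent_women: float


@dataclass(frozen=True)
class CohortDescriptives:
    rows: tuple[CohortRow, ...]
    total_n: int
    total_mean_age: float
    total_percent_women: float

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "institution": r.label,
                "n": r.n,
                "percent": round(100 * r.n / self.total_n, 1),
                "mean_age": round(r.mean_age, 1),
                "percent_women": round(r.percent_women, 1),
            }
            for r in self.rows
        ]
        records.append(
            {
                "institution": "Total",
                "n": self.total_n,
                "percent": 100.0,
                "mean_age": round(self.total_mean_age, 1),
                "percent_women": round(self.total_percent_women, 1),
            }
        )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_markdown(self) -> str:
        frame = self.to_frame()
        header = "| " + " | ".join(frame.columns) + " |"
        sep = "|" + "|".join("---" for _ in frame.columns) + "|"
        body = [
            "| " + " | ".join(str(v) for v in row) + " |"
            for row in frame.itertuples(index=False)
        ]
        return "\n".join([header, sep, *body])


def descriptives(cohorts: Sequence) -> CohortDescriptives:
    """Aggregate per-cohort descriptive rows into a pooled summary.

    ``cohorts`` may be :class:`~fedfpm.synthetic_cohorts.CohortProfile`
    objects, ``(label, n, mean_age, percent_women)`` tuples, or anything
    with ``agent_id``/``n_patients``/``mean_age``/``prop_women``
    attributes. Percentages are accepted on either the 0–1 or 0–100
    scale (women share above 1 is read as a percentage).
    """
    rows: list[CohortRow] = []
    for c in cohorts:
        if isinstance(c, tuple):
            label, n, age, women = c
        else:
            label, n, age = c.agent_id, c.n_patients, c.mean_age
            women = c.prop_women
        women = float(women)
        if women <= 1:
            women *= 100.0
        if n < 1:
            raise ValueError(f"cohort {label!r} has no patients")
        rows.append(CohortRow(label, int(n), float(age), women))
    if not rows:
        raise ValueError("need at least one cohort")
    total_n = sum(r.n for r in rows)
    mean_age = sum(r.n * r.mean_age for r in rows) / total_n
    pct_women = sum(r.n * r.percent_women for r in rows) / total_n
    return CohortDescriptives(
        rows=tuple(rows),
        total_n=total_n,
        total_mean_age=mean_age,
        total_percent_women=pct_women,
    )


@dataclass(frozen=True)
class RuleReport:
    """Rendered view of one model's rules, with the run configuration."""

    min_support: str
    min_confidence: str
    agents: tuple[str, ...]
    rows: tuple[dict, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            list(self.rows),
            columns=["antecedent", "consequent", "confidence", "lift"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_text(self) -> str:
        lines = [
            f"model: min_support={self.min_support} "
            f"min_confidence={self.min_confidence} "
            f"agents={', '.join(self.agents) if self.agents else '-'}",
            "",
        ]
        if not self.rows:
            lines.append("(no rules)")
            return "\n".join(lines)
        width = max(len(r["antecedent"]) for r in self.rows)
        for r in self.rows:
            lines.append(
                f"{r['antecedent']:<{width}} ≥ {r['consequent']}"
                f"   confidence={r['confidence']}  lift={r['lift']}"
            )
        return "\n".join(lines)


def render_rule_report(
    rules: Sequence[AssociationRule],
    config: MiningConfig,
    agents: Sequence[str] = (),
    precision: int = 3,
    separator: str = ITEM_SEPARATOR,
) -> RuleReport:
    """Render rules (descending lift) to a report object.

    Stored statistics stay exact; rounding to ``precision`` decimals
    happens here only.
    """
    rows = tuple(
        {
            "antecedent": separator.join(r.antecedent),
            "consequent": separator.join(r.consequent),
            "confidence": round(float(r.confidence), precision),
            "lift": round(float(r.lift), precision),
        }
        for r in sort_rules(rules)
    )
    return RuleReport(
        min_support=str(config.min_support),
        min_confidence=str(config.min_confidence),
        agents=tuple(agents),
        rows=rows,
    )


def read_rule_csv(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for rule CSVs written by :class:`RuleReport`."""
    frame = pd.read_csv(
        path, dtype={"antecedent": str, "consequent": str}, keep_default_na=False
    )
    expected = ["antecedent", "consequent", "confidence", "lift"]
    if list(frame.columns) != expected:
        raise ValueError(f"rule CSV must have columns {expected}")
    return frame
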