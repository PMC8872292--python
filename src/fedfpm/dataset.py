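"""Per-agent transaction data: the unit of patient-level data that never
leaves its agent.

Each transaction is one patient's set of present binary attributes
(chronic conditions, demographic categories, polypharmacy, outcome). CSV
round-trip uses one 0/1 column per item plus ``patient_id``, with a JSON
sidecar carrying provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rulestats import Itemset, canonical


@dataclass
class TransactionDataset:
    """One agent's patient-level itemset records.

    ``items`` is the agent's full variable schema — an item may be listed
    even if no patient presents it, and schemas may differ across agents
    (heterogeneous cohorts).
    """

    agent_id: str
    items: Itemset
    transactions: list[Itemset]
    ages: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.items != canonical(self.items):
            raise ValueError("item schema must be sorted and duplicate-free")
        schema = set(self.items)
        self.transactions = [canonical(t) for t in self.transactions]
        for t in self.transactions:
            extra = set(t) - schema
            if extra:
                raise ValueError(
                    f"transaction items {sorted(extra)} outside agent schema"
                )
        if self.ages is not None and len(self.ages) != len(self.transactions):
            raise ValueError("ages must align with transactions")

    @property
    def n(self) -> int:
        return len(self.transactions)

    def to_frame(self) -> pd.DataFrame:
        """0/1 indicator matrix, one row per patient, one column per item."""
        data = np.zeros((self.n, len(self.items)), dtype=np.int8)
        col = {item: j for j, item in enumerate(self.items)}
        for i, t in enumerate(self.transactions):
            for item in t:
                data[i, col[item]] = 1
        frame = pd.DataFrame(data, columns=list(self.items))
        frame.insert(0, "patient_id", [f"{self.agent_id}-{i:05d}" for i in range(self.n)])
        return frame

    @classmethod
    def from_frame(cls, agent_id: str, frame: pd.DataFrame) -> "TransactionDataset":
        cols = [c for c in frame.columns if c != "patient_id"]
        items = canonical(cols)
        values = frame[list(items)].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("indicator matrix must contain only 0/1 cells")
        transactions = [
            tuple(item for item, v in zip(items, row) if v) for row in values
        ]
        return cls(agent_id=agent_id, items=items, transactions=transactions)


def write_cohort(
    dataset: TransactionDataset, out_dir: str | Path, seed: int | None = None
) -> tuple[Path, Path]:
    """Write ``<agent_id>.csv`` plus a ``<agent_id>.meta.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{dataset.agent_id}.csv"
    meta_path = out_dir / f"{dataset.agent_id}.meta.json"
    dataset.to_frame().to_csv(csv_path, index=False)
    meta = {
        "agent_id": dataset.agent_id,
        "n": dataset.n,
        "seed": seed,
        "item_catalog": list(dataset.items),
    }
    if dataset.ages is not None:
        meta["observed_mean_age"] = round(float(np.mean(dataset.ages)), 2)
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path, meta_path


def read_cohort(csv_path: str | Path) -> TransactionDataset:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    return TransactionDataset.from_frame(csv_path.stem, frame)


def read_cohort_dir(directory: str | Path) -> list[TransactionDataset]:
    """Load every per-agent CSV in a directory, sorted by agent id."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no per-agent CSV files found in {directory}")
    return [read_cohort(p) for p in paths]


def pool(datasets: Sequence[TransactionDataset], agent_id: str = "pooled") -> TransactionDataset:
    """Concatenate agents into one centralized dataset (for oracles/tests)."""
    items = canonical([it for ds in datasets for it in ds.items])
    transactions = [t for ds in datasets for t in ds.transactions]
    return TransactionDataset(agent_id=agent_id, items=items, transactions=transactions)


def split_dataset(
    dataset: TransactionDataset, n_agents: int, rng: np.random.Generator
) -> list[TransactionDataset]:
    """Random partition of one dataset into agents with identical schemas."""
    if n_agents < 1:
        raise ValueError("need at least one agent")
    assignment = rng.integers(0, n_agents, size=dataset.n)
    return [
        TransactionDataset(
            agent_id=f"{dataset.agent_id}-part{k}",
            items=dataset.items,
            transactions=[
                t for t, a in zip(dataset.transactions, assignment) if a == k
            ],
        )
        for k in range(n_agents)
    ]
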