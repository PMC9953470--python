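"""Labeled AP-shape datasets: assembly, drug splits, folds, persistence.

A dataset row is one 1000-point AP shape (mV, not normalized — the network
operates on raw voltages) with a one-hot TdP-risk label over
(high, intermediate, low) and per-sample provenance (drug, Hill-sample
index, Cmax multiple).  At full scale a drug contributes
2000 samples × 4 Cmax multiples = 8000 shapes, of which one subsample per
drug enters a dataset; the canonical splits are 12 training drugs
(24,000 rows at 2000/drug) and 16 test drugs (32,000 rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

CLASS_ORDER = ("high", "intermediate", "low")
TRACE_LEN = 1000
CMAX_MULTIPLES = (1, 2, 3, 4)


@dataclass
class APDataset:
    x: np.ndarray       # [n x TRACE_LEN] float32, mV
    y: np.ndarray       # [n x 3] one-hot over CLASS_ORDER
    meta: pd.DataFrame  # columns: drug_id, hill_sample_index, cmax_multiple

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.float32)
        if self.x.ndim != 2 or self.x.shape[1] != TRACE_LEN:
            raise ValueError(f"x must be [n x {TRACE_LEN}], got {self.x.shape}")
        n = len(self.x)
        if self.y.shape != (n, len(CLASS_ORDER)):
            raise ValueError("y must be one-hot [n x 3]")
        if not np.allclose(self.y.sum(axis=1), 1.0):
            raise ValueError("one-hot rows must sum to 1")
        if len(self.meta) != n:
            raise ValueError("meta length must equal n_samples")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def labels(self) -> np.ndarray:
        """Integer class labels (argmax of one-hot)."""
        return self.y.argmax(axis=1)

    def subset(self, idx: np.ndarray) -> "APDataset":
        return APDataset(self.x[idx], self.y[idx],
                         self.meta.iloc[idx].reset_index(drop=True))

    def save(self, path) -> None:
        """NPZ container: arrays plus the meta table column-wise."""
        np.savez_compressed(
            path, x=self.x, y=self.y,
            drug_id=self.meta["drug_id"].to_numpy(dtype="U64"),
            hill_sample_index=self.meta["hill_sample_index"].to_numpy(dtype=np.int64),
            cmax_multiple=self.meta["cmax_multiple"].to_numpy(dtype=np.int64),
        )

    @classmethod
    def load(cls, path) -> "APDataset":
        with np.load(path) as z:
            meta = pd.DataFrame({
                "drug_id": z["drug_id"].astype(str),
                "hill_sample_index": z["hill_sample_index"],
                "cmax_multiple": z["cmax_multiple"],
            })
            return cls(z["x"], z["y"], meta)


@dataclass
class SplitPlan:
    """Which drugs train and which test, plus fold count and seed."""

    train_drugs: list[str]
    test_drugs: list[str]
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_drugs) & set(self.test_drugs)
        if overlap:
            raise ValueError(f"train/test drugs overlap: {sorted(overlap)}")


def one_hot(label: str) -> np.ndarray:
    row = np.zeros(len(CLASS_ORDER), dtype=np.float32)
    row[CLASS_ORDER.index(label)] = 1.0
    return row


def assemble(
    traces_by_drug: Mapping[str, Mapping[int, np.ndarray]],
    labels: Mapping[str, str],
    subsample_per_drug: int | str = "all",
    seed: int = 0,
) -> APDataset:
    """Stack per-drug, per-Cmax-multiple trace blocks into one dataset.

    ``traces_by_drug[drug][multiple]`` is an [n x 1000] block of selected AP
    shapes (rows ordered by Hill-sample index).  Every drug must contribute
    all four Cmax multiples.  ``subsample_per_drug`` draws that many shapes
    per drug without replacement from the drug's pooled shapes
    (deterministic given ``seed``); ``"all"`` keeps everything.
    """
    rng = np.random.default_rng(seed)
    xs, ys, metas = [], [], []
    for drug in sorted(traces_by_drug):
        if drug not in labels:
            raise ValueError(f"no risk label for drug {drug!r}")
        blocks = traces_by_drug[drug]
        for mult in CMAX_MULTIPLES:
            if mult not in blocks:
                raise ValueError(f"drug {drug!r} is missing Cmax multiple {mult}")
        x_drug = np.concatenate([np.asarray(blocks[m], dtype=np.float32)
                                 for m in CMAX_MULTIPLES])
        meta_drug = pd.DataFrame({
            "drug_id": drug,
            "hill_sample_index": np.concatenate(
                [np.arange(len(blocks[m])) for m in CMAX_MULTIPLES]),
            "cmax_multiple": np.concatenate(
                [np.full(len(blocks[m]), m) for m in CMAX_MULTIPLES]),
        })
        if subsample_per_drug != "all":
            k = int(subsample_per_drug)
            if k > len(x_drug):
                raise ValueError(
                    f"subsample {k} exceeds {len(x_drug)} shapes for {drug!r}")
            idx = np.sort(rng.choice(len(x_drug), size=k, replace=False))
            x_drug = x_drug[idx]
            meta_drug = meta_drug.iloc[idx].reset_index(drop=True)
        xs.append(x_drug)
        ys.append(np.tile(one_hot(labels[drug]), (len(x_drug), 1)))
        metas.append(meta_drug)
    return APDataset(np.concatenate(xs), np.concatenate(ys),
                     pd.concat(metas, ignore_index=True))


def make_folds(dataset: APDataset, k: int = 10, seed: int = 0) -> np.ndarray:
    """Per-sample fold assignment in 0..k-1: stratified by risk class,
    fold sizes within one sample of each other, deterministic by seed."""
    n = len(dataset)
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(n, dtype=np.int64)
    for fold, (_, val_idx) in enumerate(skf.split(dataset.x, dataset.labels)):
        assign[val_idx] = fold
    return assign
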