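"""Repeated-testing evaluation of the three-class risk classifier.

The evaluation harness draws, for each of ``n_repeats`` repeats, a fixed
number of AP shapes per drug from the test pool (without replacement within
a repeat), classifies them, reduces each class one-vs-rest and computes
AUC, sensitivity, specificity and likelihood ratios

    LR+ = sensitivity / max(1 − specificity, ε)
    LR− = (1 − sensitivity) / max(specificity, ε)

(ε guards divisions when specificity is 1).  Reported point values are
means over repeats; intervals are central 95% percentile intervals of the
repeat distribution.  Confusion matrices are averaged over repeats and then
row-normalized.  AUC is the Mann-Whitney pair statistic (ties count 0.5) of
the class probability against the one-vs-rest label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .dataset import APDataset, CLASS_ORDER

DEFAULT_EPS = 1e-4


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for one class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no negative samples")
    return (counts.tp / (counts.tp + counts.fn),
            counts.tn / (counts.tn + counts.fp))


def likelihood_ratios(sensitivity: float, specificity: float,
                      eps: float = DEFAULT_EPS) -> tuple[float, float]:
    """(LR+, LR−) with a small-ε guard on both denominators."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity/specificity must be in [0,1]")
    lr_plus = sensitivity / max(1.0 - specificity, eps)
    lr_minus = (1.0 - sensitivity) / max(specificity, eps)
    return lr_plus, lr_minus


def _auc_mann_whitney(scores: np.ndarray, positive: np.ndarray) -> float:
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one-vs-rest labels are single-class")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 per pair
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_auc_ovr(probs: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Per-class one-vs-rest AUC of probs[:, c] against label == c.

    Classes absent from ``labels`` (or covering all of them) have no
    defined one-vs-rest AUC and are omitted; fully single-class labels
    raise."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels are single-class")
    out = {}
    for c, cls in enumerate(CLASS_ORDER):
        pos = labels == c
        if 0 < pos.sum() < len(labels):
            out[cls] = _auc_mann_whitney(probs[:, c], pos)
    return out


@dataclass
class RiskEvalReport:
    """Per-class metrics as (point, ci_low, ci_high), plus the normalized
    confusion matrix (rows = true class, columns = predicted, rows sum 1)."""

    metrics: dict[str, dict[str, tuple[float, float, float]]]
    confusion: np.ndarray
    n_repeats: int
    per_drug: int
    seed: int

    def __post_init__(self) -> None:
        rows = self.confusion.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        for cls, m in self.metrics.items():
            for name, (pt, lo, hi) in m.items():
                if not lo - 1e-12 <= pt <= hi + 1e-12:
                    raise ValueError(
                        f"{cls}/{name}: point {pt} outside CI [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "per_drug": self.per_drug,
            "seed": self.seed,
            "classes": {
                cls: {name: {"point": pt, "ci_low": lo, "ci_high": hi}
                      for name, (pt, lo, hi) in m.items()}
                for cls, m in self.metrics.items()
            },
            "confusion_matrix": self.confusion.tolist(),
            "class_order": list(CLASS_ORDER),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


_METRIC_NAMES = ("auc", "sensitivity", "specificity", "lr_plus", "lr_minus")


def repeated_test(model, pool: APDataset, n_repeats: int = 10000,
                  per_drug: int = 100, seed: int = 0,
                  eps: float = DEFAULT_EPS) -> RiskEvalReport:
    """Repeat: draw ``per_drug`` shapes per drug, classify, score.

    ``model`` needs a ``predict_proba([n x 1000]) -> [n x 3]`` method.
    Inference is deterministic, so class probabilities are computed once for
    the whole pool and repeats only resample indices.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    drug_idx: dict[str, np.ndarray] = {
        str(d): np.flatnonzero((pool.meta["drug_id"] == d).to_numpy())
        for d in pool.meta["drug_id"].unique()
    }
    for d, idx in drug_idx.items():
        if len(idx) < per_drug:
            raise ValueError(
                f"drug {d!r} has only {len(idx)} samples < per_drug={per_drug}")
    probs_all = model.predict_proba(pool.x)
    labels_all = pool.labels
    n_cls = len(CLASS_ORDER)

    per_metric = {cls: {name: np.empty(n_repeats) for name in _METRIC_NAMES}
                  for cls in CLASS_ORDER}
    conf_sum = np.zeros((n_cls, n_cls))

    for r in range(n_repeats):
        take = np.concatenate([
            rng.choice(idx, size=per_drug, replace=False)
            for _, idx in sorted(drug_idx.items())
        ])
        probs = probs_all[take]
        labels = labels_all[take]
        pred = probs.argmax(axis=1)
        conf = np.zeros((n_cls, n_cls))
        for c_true in range(n_cls):
            mask = labels == c_true
            if mask.any():
                conf[c_true] = np.bincount(pred[mask], minlength=n_cls) / mask.sum()
        conf_sum += conf
        for c, cls in enumerate(CLASS_ORDER):
            pos = labels == c
            ppos = pred == c
            counts = ConfusionCounts(
                tp=int(np.sum(pos & ppos)), tn=int(np.sum(~pos & ~ppos)),
                fp=int(np.sum(~pos & ppos)), fn=int(np.sum(pos & ~ppos)))
            sens, spec = sens_spec(counts)
            lr_p, lr_m = likelihood_ratios(sens, spec, eps)
            rec = per_metric[cls]
            rec["auc"][r] = _auc_mann_whitney(probs[:, c], pos)
            rec["sensitivity"][r] = sens
            rec["specificity"][r] = spec
            rec["lr_plus"][r] = lr_p
            rec["lr_minus"][r] = lr_m

    metrics = {
        cls: {
            name: (float(vals.mean()),
                   float(np.quantile(vals, 0.025)),
                   float(np.quantile(vals, 0.975)))
            for name, vals in rec.items()
        }
        for cls, rec in per_metric.items()
    }
    conf_mean = conf_sum / n_repeats
    conf_norm = conf_mean / conf_mean.sum(axis=1, keepdims=True)
    return RiskEvalReport(metrics=metrics, confusion=conf_norm,
                          n_repeats=n_repeats, per_drug=per_drug, seed=seed)


def drug_level_report(model, pool: APDataset) -> dict[str, dict]:
    """Secondary view: mean class probability and majority prediction per
    drug (AP shapes from one drug are correlated)."""
    probs = model.predict_proba(pool.x)
    out = {}
    for d in pool.meta["drug_id"].unique():
        idx = np.flatnonzero((pool.meta["drug_id"] == d).to_numpy())
        mean_p = probs[idx].mean(axis=0)
        out[str(d)] = {
            "mean_probs": {cls: float(p) for cls, p in zip(CLASS_ORDER, mean_p)},
            "predicted": CLASS_ORDER[int(mean_p.argmax())],
            "true": CLASS_ORDER[int(pool.labels[idx[0]])],
            "n_shapes": int(len(idx)),
        }
    return out
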