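"""End-to-end orchestration: panel -> bootstrap -> simulate -> dataset ->
train -> evaluate.

The full-scale protocol (2000 Hill samples/drug, 1000 beats, 10,000 test
repeats) and a reduced desk-scale variant share this code path; every knob
is an argument.  The reduced defaults here — a handful of Hill samples per
drug, 20 beats continued from the shipped drug-free steady state with the
selection window over the last 5 beats, 15 training epochs, 100 evaluation
repeats — exercise the identical code as the full protocol.  Starting beats
from the converged drug-free state means drug effects on AP shape stabilize
within a few beats, which is what makes the short pacing run meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import ap_metrics, cell_sim, cnn_classifier, dataset, drug_response, risk_eval

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bootstrap_B: int = 50             # Hill samples per drug-channel
    n_hill_per_drug: int = 8          # Hill samples actually simulated
    multiples: tuple[int, ...] = (1, 2, 3, 4)
    n_beats: int = 20
    window: tuple[int, int] = (16, 20)  # beat-selection window (1-based)
    epochs: int = 15
    folds: int = 3
    learning_rate: float = 0.01
    eval_repeats: int = 100
    eval_per_drug: int = 8
    seed: int = 0


@dataclass
class PipelineResult:
    hill_samples: dict
    train_ds: "dataset.APDataset"
    test_ds: "dataset.APDataset"
    train_result: "cnn_classifier.TrainResult"
    report: "risk_eval.RiskEvalReport"


def simulate_panel(
    panel: drug_response.DoseResponsePanel,
    hill_samples: Mapping[tuple[str, str], drug_response.HillSampleSet],
    sample_indices: np.ndarray,
    multiples: tuple[int, ...],
    n_beats: int,
    window: tuple[int, int],
    initial: cell_sim.CellState | None = None,
) -> dict[str, dict[int, np.ndarray]]:
    """Run the paced simulation for every (drug, Hill sample, multiple) and
    return the selected AP shape per combination,
    ``traces[drug][multiple][row] = 1000-point trace`` with rows ordered by
    Hill-sample index."""
    initial = initial or cell_sim.steady_state()
    traces: dict[str, dict[int, np.ndarray]] = {}
    for drug in panel.drugs:
        channels = panel.channels_measured(drug)
        per_mult: dict[int, list[np.ndarray]] = {m: [] for m in multiples}
        for si in sample_indices:
            hill = {ch: hill_samples[(drug, ch)].samples[int(si)] for ch in channels}
            for mult in multiples:
                scales = cell_sim.drug_scales_from_samples(
                    hill, panel.cmax[drug], mult)
                cfg = cell_sim.CellModelConfig(drug_scales=scales)
                series = cell_sim.simulate_drug(initial, cfg, n_beats=n_beats)
                beat = ap_metrics.select_beat(series, window=window)
                per_mult[mult].append(beat.v)
        traces[drug] = {m: np.asarray(v) for m, v in per_mult.items()}
    return traces


def run_pipeline(panel: drug_response.DoseResponsePanel,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Reduced-scale end-to-end run on one drug panel.

    Hill samples per drug are split in half: even positions build the
    training set, odd positions the held-out test pool (the drugs of this
    panel appear in both — at desk scale the split is across experimental
    uncertainty samples, not drugs).
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)

    logger.info("bootstrapping %d drugs, B=%d", len(panel.drugs), cfg.bootstrap_B)
    hill_samples = drug_response.bootstrap_panel(panel, B=cfg.bootstrap_B,
                                                 seed=cfg.seed)

    n_sim = min(cfg.n_hill_per_drug, cfg.bootstrap_B)
    sample_indices = np.sort(rng.choice(cfg.bootstrap_B, size=n_sim, replace=False))
    logger.info("simulating %d Hill samples x %d multiples x %d drugs, %d beats",
                n_sim, len(cfg.multiples), len(panel.drugs), cfg.n_beats)
    traces = simulate_panel(panel, hill_samples, sample_indices,
                            cfg.multiples, cfg.n_beats, cfg.window)

    half = {d: {m: blk[0::2] for m, blk in traces[d].items()} for d in traces}
    other = {d: {m: blk[1::2] for m, blk in traces[d].items()} for d in traces}
    train_ds = dataset.assemble(half, panel.risk_label, seed=cfg.seed)
    test_ds = dataset.assemble(other, panel.risk_label, seed=cfg.seed + 1)

    logger.info("training CNN: %d rows, %d epochs, %d folds",
                len(train_ds), cfg.epochs, cfg.folds)
    tr = cnn_classifier.train(
        train_ds,
        cnn_classifier.TrainConfig(epochs=cfg.epochs, folds=cfg.folds,
                                   learning_rate=cfg.learning_rate,
                                   seed=cfg.seed),
    )

    logger.info("repeated testing: %d repeats, %d shapes/drug",
                cfg.eval_repeats, cfg.eval_per_drug)
    report = risk_eval.repeated_test(tr.model, test_ds,
                                     n_repeats=cfg.eval_repeats,
                                     per_drug=cfg.eval_per_drug,
                                     seed=cfg.seed)
    return PipelineResult(hill_samples, train_ds, test_ds, tr, report)
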