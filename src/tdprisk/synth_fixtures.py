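"""Seeded synthetic fixtures: drug panels and surrogate AP shapes.

Two generators make every pipeline stage testable without external data:

* :func:`make_drug_panel` / :func:`default_panel` emulate a seven-channel
  patch-clamp dose-response panel.  Risk classes follow the standard
  torsadogenic pharmacology: a high-risk drug blocks IKr (hERG) far below
  its therapeutic concentration; an intermediate-risk drug blocks IKr near
  2x Cmax; a low-risk drug either touches no channel in the therapeutic
  range or pairs mild IKr block with offsetting ICaL (or Na+) block.

* :func:`make_surrogate_aps` builds parametric AP-shaped traces (fast
  upstroke, decaying spike, plateau, sigmoidal repolarization, optional
  EAD bump) with class-dependent APD, so classifier and evaluation tests
  never pay the ODE-integration cost.  Surrogates emulate the geometry of
  simulated APs, not any real drug.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset import APDataset, CLASS_ORDER, TRACE_LEN
from .drug_response import (
    CHANNELS,
    DoseResponseMeasurement,
    DoseResponsePanel,
    HillParams,
    hill_block,
)

import pandas as pd


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Ground-truth channel-block profile of one synthetic drug."""

    drug_id: str
    risk_label: str
    # channel -> (ic50 µM, hill, replicate noise σ on the block fraction)
    channel_profile: Mapping[str, tuple[float, float, float]]
    cmax: float  # µM
    concentrations: tuple[float, ...] | None = None  # default: log-spaced
    replicates: int = 6

    def conc_grid(self) -> np.ndarray:
        if self.concentrations is not None:
            c = np.asarray(self.concentrations, dtype=float)
        else:
            # four points log-spaced around Cmax, covering 1/4x .. 16x
            c = self.cmax * np.array([0.25, 1.0, 4.0, 16.0])
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        return c


def make_drug_panel(specs: Sequence[SyntheticDrugSpec], seed: int = 0) -> DoseResponsePanel:
    """Panel of noisy Hill-curve measurements from ground-truth profiles.

    Replicate block fractions are hill_block(D) + N(0, σ), clamped to [0,1];
    deterministic given ``seed``.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    rng = np.random.default_rng(seed)
    measurements = []
    for spec in specs:
        conc = spec.conc_grid()
        for ch in CHANNELS:
            if ch not in spec.channel_profile:
                continue
            ic50, hill, sigma = spec.channel_profile[ch]
            params = HillParams(ic50=ic50, hill=hill)
            for d in conc:
                true_block = float(hill_block(float(d), params))
                for _ in range(spec.replicates):
                    b = true_block + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
                    measurements.append(DoseResponseMeasurement(
                        spec.drug_id, ch, float(d),
                        float(np.clip(b, 0.0, 1.0))))
    return DoseResponsePanel(
        measurements=measurements,
        cmax={s.drug_id: s.cmax for s in specs},
        risk_label={s.drug_id: s.risk_label for s in specs},
    )


def default_drug_specs() -> list[SyntheticDrugSpec]:
    """Nine drugs, three per risk class, designed so the full pipeline
    (simulate -> select -> train -> evaluate) separates the classes."""
    s = 0.02  # replicate noise on block fractions
    return [
        # high risk: selective IKr block with IC50 well below Cmax
        SyntheticDrugSpec("synthhigh1", "high",
                          {"IKr": (0.125, 0.9, s)}, cmax=1.0),
        SyntheticDrugSpec("synthhigh2", "high",
                          {"IKr": (0.08, 1.2, s), "INaL": (40.0, 1.0, s)}, cmax=0.5),
        SyntheticDrugSpec("synthhigh3", "high",
                          {"IKr": (0.3, 1.0, s)}, cmax=2.0),
        # intermediate risk: IKr IC50 near 2x Cmax
        SyntheticDrugSpec("synthint1", "intermediate",
                          {"IKr": (2.0, 1.0, s)}, cmax=1.0),
        SyntheticDrugSpec("synthint2", "intermediate",
                          {"IKr": (1.8, 1.2, s)}, cmax=0.8),
        SyntheticDrugSpec("synthint3", "intermediate",
                          {"IKr": (3.5, 0.9, s)}, cmax=1.5),
        # low risk: no block in the therapeutic range, or offsetting
        # ICaL+IKr / Na-channel block
        SyntheticDrugSpec("synthlow1", "low",
                          {"IKr": (60.0, 1.0, s)}, cmax=1.0),
        SyntheticDrugSpec("synthlow2", "low",
                          {"ICaL": (7.2, 1.5, s), "IKr": (7.2, 1.5, s)}, cmax=0.6),
        SyntheticDrugSpec("synthlow3", "low",
                          {"INa": (30.0, 1.0, s), "INaL": (18.0, 1.0, s),
                           "IKr": (90.0, 1.0, s)}, cmax=1.2),
    ]


def default_panel(seed: int = 0) -> DoseResponsePanel:
    """The canonical 9-drug synthetic panel (3 drugs per risk class)."""
    return make_drug_panel(default_drug_specs(), seed=seed)


# ---------------------------------------------------------------------------
# Surrogate AP shapes
# ---------------------------------------------------------------------------

def _default_shift() -> dict[str, float]:
    return {"high": 160.0, "intermediate": 70.0, "low": 0.0}


def _default_ead_p() -> dict[str, float]:
    return {"high": 0.6, "intermediate": 0.15, "low": 0.0}


@dataclass(frozen=True)
class SurrogateAPParams:
    """Parametric AP template: class-shifted APD and optional EAD bump."""

    baseline_apd: float = 280.0          # ms, APD90 of the low class
    apd_shift: Mapping[str, float] = field(default_factory=_default_shift)
    ead_probability: Mapping[str, float] = field(default_factory=_default_ead_p)
    plateau_height: float = 25.0         # mV, early plateau level
    noise_sigma: float = 0.05            # mV, smoothed additive noise; kept
                                         # small so noise slopes stay well
                                         # below the EAD dV/dt threshold
    resting_v: float = -85.0             # mV
    spike_amp: float = 12.0              # mV, upstroke overshoot above plateau
    repol_width: float = 12.0            # ms, repolarization sigmoid width
    dt_ms: float = 2.0

    def __post_init__(self) -> None:
        for cls, p in self.ead_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ead_probability[{cls}] must be in [0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def surrogate_trace(apd90: float, ead: bool, params: SurrogateAPParams,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """One 1000-point surrogate AP with the requested APD90."""
    p = params
    t = np.arange(TRACE_LEN) * p.dt_ms
    amp = p.plateau_height - p.resting_v
    spike = p.spike_amp * np.exp(-t / 15.0)
    # peak is realized at the second sample (t = dt); place the sigmoid
    # center so the APD90 threshold crossing lands at the requested APD90
    peak_est = p.resting_v + amp + p.spike_amp * np.exp(-p.dt_ms / 15.0)
    thr_gap = 0.1 * (peak_est - p.resting_v)  # V_thr - resting at level 0.9
    tc = apd90 - p.repol_width * np.log(amp / thr_gap - 1.0)
    v = p.resting_v + amp / (1.0 + np.exp((t - tc) / p.repol_width)) + spike
    if ead:
        center = 0.35 * apd90 + 0.45 * tc  # mid-repolarization
        v = v + 10.0 * np.exp(-((t - center) ** 2) / (2.0 * 15.0**2))
    v[0] = p.resting_v  # pre-upstroke sample
    if rng is not None and p.noise_sigma > 0:
        noise = gaussian_filter1d(rng.normal(0.0, 1.0, TRACE_LEN), sigma=10.0)
        sd = noise.std()
        if sd > 0:
            v = v + noise * (p.noise_sigma / sd)
    return v


def make_surrogate_aps(n_per_class: int,
                       params: SurrogateAPParams | None = None,
                       seed: int = 0) -> APDataset:
    """Labeled surrogate dataset, ``n_per_class`` traces per risk class.

    Traces of a class share the class APD (baseline + shift) and draw an
    EAD bump with the class probability.  Each class is spread over three
    pseudo-drugs so per-drug evaluation draws are meaningful.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    p = params or SurrogateAPParams()
    rng = np.random.default_rng(seed)
    xs, ys, drugs, sample_idx, mults = [], [], [], [], []
    for c, cls in enumerate(CLASS_ORDER):
        apd_c = p.baseline_apd + p.apd_shift[cls]
        for i in range(n_per_class):
            ead = bool(rng.random() < p.ead_probability[cls])
            xs.append(surrogate_trace(apd_c, ead, p, rng))
            row = np.zeros(len(CLASS_ORDER), dtype=np.float32)
            row[c] = 1.0
            ys.append(row)
            drugs.append(f"{cls}-s{i % 3}")
            sample_idx.append(i)
            mults.append(1 + i % 4)
    meta = pd.DataFrame({
        "drug_id": drugs,
        "hill_sample_index": sample_idx,
        "cmax_multiple": mults,
    })
    return APDataset(np.asarray(xs, dtype=np.float32), np.asarray(ys), meta)
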