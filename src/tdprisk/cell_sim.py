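"""Paced ventricular myocyte simulation under static multichannel drug block.

The cell model is the O'Hara-Rudy (ORd) dynamic human ventricular myocyte
with the CiPA conductance re-optimization of IKr, IKs, IK1, ICaL and INaL
(numba kernel in :mod:`tdprisk._ord`).  Static drug block enters as a
per-channel multiplier on the maximal conductance,

    I_ion = s_ion · G_ion · m_ion (V − E_ion),   s_ion = 1 − block(D),

so a drug-free simulation (all s_ion = 1) is bit-identical to the
unmodified model.  The standard protocol paces the cell at a 2000 ms cycle
length (bradycardia, 30 bpm) with a −80 µA/µF, 0.5 ms stimulus, integrating
at dt = 0.1 ms (forward Euler + Rush-Larsen gates) and recording V every
2 ms: 1000 samples per beat.

Simulations start from a drug-free steady state reached after 10,000 paced
beats; that state ships as a versioned fixture (see :func:`steady_state`)
and can be regenerated with :func:`run_to_steady` or the CLI.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from . import _ord
from .ap_metrics import APTrace
from .drug_response import CHANNELS, HillParams, conductance_scale

CELL_TYPES = ("endo", "epi", "M")

STEADY_STATE_FIXTURE = "steady_state_endo_cl2000.json"


class NumericalBlowupError(RuntimeError):
    """Integration produced a non-finite or out-of-range membrane potential."""


def _load_conductance_config() -> dict:
    ref = importlib.resources.files("tdprisk.data") / "ord_conductances.yaml"
    return yaml.safe_load(ref.read_text())


_COND = _load_conductance_config()


def _neutral_scales() -> dict[str, float]:
    return {ch: 1.0 for ch in CHANNELS}


@dataclass
class CellModelConfig:
    """Configuration of one paced-cell simulation."""

    drug_scales: dict[str, float] = field(default_factory=_neutral_scales)
    cell_type: str = "endo"
    stim_amplitude: float = -80.0  # µA/µF
    stim_duration_ms: float = 0.5
    cl_ms: float = 2000.0
    dt_ms: float = 0.1
    record_dt_ms: float = 2.0
    # the Na+ upstroke (~1 ms) is stiffer than the 0.1 ms base step: the
    # first upstroke_window_ms of each cycle use dt/upstroke_substeps
    upstroke_window_ms: float = 10.0
    upstroke_substeps: int = 10
    base_conductances: dict[str, float] = field(
        default_factory=lambda: dict(_COND["base_conductances"]))
    cipa_rescale: dict[str, float] = field(
        default_factory=lambda: dict(_COND["cipa_rescale"]))
    apply_cipa_rescale: bool = True

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        for ch, s in self.drug_scales.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r} in drug_scales")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"drug scale for {ch} must be in [0,1], got {s}")
        for ch in CHANNELS:
            self.drug_scales.setdefault(ch, 1.0)
        if abs(round(self.record_dt_ms / self.dt_ms) * self.dt_ms
               - self.record_dt_ms) > 1e-9:
            raise ValueError("dt_ms must divide record_dt_ms")
        if abs(round(self.cl_ms / self.record_dt_ms) * self.record_dt_ms
               - self.cl_ms) > 1e-9:
            raise ValueError("record_dt_ms must divide cl_ms")

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.cl_ms / self.record_dt_ms))

    def kernel_params(self) -> np.ndarray:
        """Assemble the parameter vector consumed by the numba kernel:
        base conductance × cell-type factor × CiPA rescale × drug scale."""
        g = dict(self.base_conductances)
        rescale = self.cipa_rescale if self.apply_cipa_rescale else {}
        for ch in CHANNELS:
            g[ch] = g[ch] * rescale.get(ch, 1.0) * self.drug_scales[ch]

        gncx, pnak, gkb = 0.0008, 30.0, 0.003
        cmdnmax, jrel_scale, jup_scale, epi_flag = 0.05, 1.0, 1.0, 0.0
        if self.cell_type == "epi":
            g["INaL"] *= 0.6
            g["Ito"] *= 4.0
            g["ICaL"] *= 1.2
            g["IKr"] *= 1.3
            g["IKs"] *= 1.4
            g["IK1"] *= 1.2
            gncx *= 1.1
            pnak *= 0.9
            gkb *= 0.6
            cmdnmax *= 1.3
            jup_scale = 1.3
            epi_flag = 1.0
        elif self.cell_type == "M":
            g["Ito"] *= 4.0
            g["ICaL"] *= 2.5
            g["IKr"] *= 0.8
            g["IK1"] *= 1.3
            gncx *= 1.4
            pnak *= 0.7
            jrel_scale = 1.7

        return np.array([
            g["INa"], g["INaL"], g["ICaL"], g["IKr"], g["IKs"], g["IK1"],
            g["Ito"], gncx, pnak, gkb, 3.75e-10, 2.5e-8, 0.0005,
            cmdnmax, jrel_scale, jup_scale, epi_flag,
        ])


class CellState:
    """Full model state at one instant: V, gates, concentrations, CaMK trap."""

    #: indices of gating variables bounded to [0, 1]
    _BOUNDED = range(9, 38)

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (_ord.N_STATES,):
            raise ValueError(f"state vector must have {_ord.N_STATES} entries")
        self.values = values.copy()
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            bad = _ord.STATE_NAMES[int(np.flatnonzero(~np.isfinite(v))[0])]
            raise NumericalBlowupError(f"non-finite state component {bad!r}")
        if not -150.0 <= v[0] <= 80.0:
            raise ValueError(f"membrane potential {v[0]:.1f} mV outside [-150, 80]")
        for i in self._BOUNDED:
            if not -1e-9 <= v[i] <= 1.0 + 1e-9:
                raise ValueError(
                    f"gate {_ord.STATE_NAMES[i]!r} = {v[i]:.4g} outside [0, 1]")
        if np.any(v[1:9] <= 0.0):
            bad = _ord.STATE_NAMES[1 + int(np.flatnonzero(v[1:9] <= 0)[0])]
            raise ValueError(f"concentration {bad!r} must be positive")

    @property
    def v(self) -> float:
        return float(self.values[0])

    def as_dict(self) -> dict[str, float]:
        return {n: float(x) for n, x in zip(_ord.STATE_NAMES, self.values)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CellState":
        return cls(np.array([d[n] for n in _ord.STATE_NAMES]))

    @classmethod
    def published_initial(cls) -> "CellState":
        return cls(_ord.INITIAL_STATE)


@dataclass
class BeatSeries:
    """Recorded membrane potential of a paced run, one row per beat."""

    v: np.ndarray  # [n_beats x samples_per_beat], mV
    final_state: CellState
    config_used: CellModelConfig

    @property
    def n_beats(self) -> int:
        return self.v.shape[0]

    def trace(self, beat_index: int) -> APTrace:
        """Beat by 1-based index (beats are numbered 1..n_beats)."""
        if not 1 <= beat_index <= self.n_beats:
            raise IndexError(f"beat index {beat_index} outside 1..{self.n_beats}")
        return APTrace(self.v[beat_index - 1],
                       dt_ms=self.config_used.record_dt_ms,
                       beat_index=beat_index)


def ord_rhs(state: CellState, t_in_beat: float, config: CellModelConfig) -> np.ndarray:
    """Time derivative of the full state vector at time ``t_in_beat`` (ms)
    within a cycle (stimulus current active for the first 0.5 ms)."""
    ist = (config.stim_amplitude
           if 0.0 <= t_in_beat < config.stim_duration_ms else 0.0)
    dy = _ord.rhs(state.values, ist, config.kernel_params())
    if not np.all(np.isfinite(dy)):
        bad = _ord.STATE_NAMES[int(np.flatnonzero(~np.isfinite(dy))[0])]
        raise NumericalBlowupError(f"non-finite derivative of {bad!r}")
    return dy


def ord_currents(state: CellState, t_in_beat: float,
                 config: CellModelConfig) -> dict[str, float]:
    """Individual ionic currents (µA/µF) / SR fluxes at one state."""
    ist = (config.stim_amplitude
           if 0.0 <= t_in_beat < config.stim_duration_ms else 0.0)
    cur = _ord.currents(state.values, ist, config.kernel_params())
    return {n: float(x) for n, x in zip(_ord.CURRENT_NAMES, cur)}


def _pace(state: CellState, config: CellModelConfig, n_beats: int,
          record: bool) -> tuple[np.ndarray, np.ndarray, CellState]:
    y = state.values.copy()
    out, snaps, status = _ord.pace(
        y, n_beats, config.cl_ms, config.dt_ms, config.record_dt_ms,
        config.stim_amplitude, config.stim_duration_ms,
        config.kernel_params(), record,
        config.upstroke_window_ms, config.upstroke_substeps,
    )
    if status != 0:
        raise NumericalBlowupError(
            f"numerical blowup during beat {status} "
            f"(V = {snaps[status - 1, 0]:.3g} mV)")
    return out, snaps, CellState(y)


def run_to_steady(config: CellModelConfig | None = None,
                  n_beats: int = 10000) -> tuple[CellState, np.ndarray]:
    """Drug-free pacing to steady state from the published initial conditions.

    Returns the end-of-run state and the per-beat state-change norms
    ‖state(end of beat k) − state(end of beat k−1)‖₂ (length ``n_beats − 1``),
    which quantify convergence.  Requires neutral drug scales.
    """
    config = config or CellModelConfig()
    if any(s != 1.0 for s in config.drug_scales.values()):
        raise ValueError("run_to_steady requires drug-free (all-1) scales")
    state = CellState.published_initial()
    if n_beats == 0:
        return state, np.empty(0)
    _, snaps, final = _pace(state, config, n_beats, record=False)
    norms = np.linalg.norm(np.diff(snaps, axis=0), axis=1)
    return final, norms


def simulate_drug(initial: CellState, config: CellModelConfig,
                  n_beats: int = 1000) -> BeatSeries:
    """Paced run under the drug scales in ``config``, recording every beat."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    v, _, final = _pace(initial, config, n_beats, record=True)
    return BeatSeries(v=v, final_state=final, config_used=config)


def drug_scales_from_samples(hill: Mapping[str, HillParams], cmax: float,
                             multiple: int) -> dict[str, float]:
    """Per-channel conductance scales at ``multiple``·Cmax for one Hill
    sample; channels without a measured Hill curve default to scale 1."""
    if multiple < 1:
        raise ValueError("Cmax multiple must be >= 1")
    if not cmax > 0:
        raise ValueError("cmax must be positive")
    scales = _neutral_scales()
    for ch, params in hill.items():
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
        scales[ch] = conductance_scale(multiple * cmax, params)
    return scales


# ---------------------------------------------------------------------------
# Steady-state fixture
# ---------------------------------------------------------------------------

def steady_state() -> CellState:
    """The shipped drug-free steady state (endo, CL 2000 ms, 10,000 beats)."""
    ref = importlib.resources.files("tdprisk.data") / STEADY_STATE_FIXTURE
    payload = json.loads(ref.read_text())
    return CellState.from_dict(payload["state"])


def save_steady_state(state: CellState, path, n_beats: int, cl_ms: float) -> None:
    payload = {
        "model_version": _COND["model_version"],
        "protocol": {"n_beats": n_beats, "cl_ms": cl_ms, "cell_type": "endo"},
        "state": state.as_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
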