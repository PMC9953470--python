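"""Action-potential biomarkers and the beat-selection rule.

Works on single-beat membrane-potential traces sampled on a uniform grid
(2 ms by default, 1000 points per 2000 ms cycle).  Conventions:

* resting potential = the first sample of the beat (the pre-stimulus value
  at a 2000 ms cycle length, where the diastolic interval is long);
* activation time = time of maximum dV/dt during the upstroke (before the
  peak);
* APD at level x = time from activation to the first crossing of
  V_thr = peak − x·(peak − rest) after the peak, linearly interpolated
  between samples; if the trace never repolarizes below the threshold the
  trace duration is returned and a did-not-repolarize flag is set;
* the repolarization window for slope/EAD metrics starts 50 ms after the
  peak (skipping the phase-1 notch, which can produce a brief positive
  dV/dt that is not an EAD) and ends at the APD90 crossing or trace end;
* an EAD is flagged when dV/dt exceeds +0.01 mV/ms for at least two
  consecutive samples inside that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Minimum upstroke amplitude (peak − first sample) for a valid beat, mV.
MIN_UPSTROKE_MV = 30.0

#: Repolarization window offset after the AP peak, ms.
REPOL_WINDOW_START_MS = 50.0

#: EAD detection: dV/dt threshold (mV/ms) and required consecutive samples.
EAD_SLOPE_THRESHOLD = 0.01
EAD_MIN_CONSECUTIVE = 2


@dataclass(frozen=True)
class APTrace:
    """One beat of membrane potential on a uniform time grid."""

    v: np.ndarray  # mV
    dt_ms: float = 2.0
    beat_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "v", v)
        if v.ndim != 1 or len(v) < 4:
            raise ValueError("trace must be a 1-D array with >= 4 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return len(self.v) * self.dt_ms


@dataclass(frozen=True)
class APBiomarkers:
    apd90: float
    apd50: float
    peak_v: float
    resting_v: float
    max_repol_slope: float
    ead: bool
    did_not_repolarize: bool = False

    def __post_init__(self) -> None:
        if self.apd50 > self.apd90 + 1e-9:
            raise ValueError("APD50 cannot exceed APD90")
        if not self.resting_v < self.peak_v:
            raise ValueError("resting potential must be below peak")


def _upstroke(trace: APTrace) -> tuple[int, int, float, float]:
    """(activation index, peak index, resting_v, peak_v); validates upstroke."""
    v = trace.v
    resting_v = float(v[0])
    i_peak = int(np.argmax(v))
    peak_v = float(v[i_peak])
    if peak_v - resting_v <= MIN_UPSTROKE_MV:
        raise ValueError(
            f"no valid upstroke: peak - first sample = {peak_v - resting_v:.1f} mV "
            f"<= {MIN_UPSTROKE_MV} mV"
        )
    dv = np.diff(v[: i_peak + 1])
    i_act = int(np.argmax(dv)) if len(dv) else 0
    return i_act, i_peak, resting_v, peak_v


def apd_flagged(trace: APTrace, level: float) -> tuple[float, bool]:
    """APD at repolarization fraction ``level`` and a did-not-repolarize flag."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    v = trace.v
    dt = trace.dt_ms
    i_act, i_peak, resting_v, peak_v = _upstroke(trace)
    thr = peak_v - level * (peak_v - resting_v)
    t_act = i_act * dt
    below = np.flatnonzero(v[i_peak + 1:] < thr)
    if len(below) == 0:
        return trace.duration_ms, True
    i_cross = i_peak + 1 + int(below[0])  # first sample below threshold
    v_hi, v_lo = v[i_cross - 1], v[i_cross]
    # linear interpolation inside the bracketing interval
    frac = (v_hi - thr) / (v_hi - v_lo) if v_hi != v_lo else 0.0
    t_cross = (i_cross - 1 + frac) * dt
    return t_cross - t_act, False


def apd(trace: APTrace, level: float) -> float:
    """APD at repolarization fraction ``level`` (0.9 -> APD90), ms."""
    value, _ = apd_flagged(trace, level)
    return value


def _repol_window(trace: APTrace) -> tuple[int, int]:
    """Sample index range [lo, hi) of the repolarization window."""
    _, i_peak, _, _ = _upstroke(trace)
    lo = i_peak + int(np.ceil(REPOL_WINDOW_START_MS / trace.dt_ms))
    apd90, dnr = apd_flagged(trace, 0.9)
    if dnr:
        hi = len(trace.v)
    else:
        i_act, _, _, _ = _upstroke(trace)
        hi = min(len(trace.v), int(np.ceil((apd90 + i_act * trace.dt_ms) / trace.dt_ms)) + 1)
    return lo, hi


def max_repol_slope(trace: APTrace) -> float:
    """Maximum finite-difference dV/dt (mV/ms) over the repolarization window.

    Positive values indicate a depolarizing deflection (EAD-like); a clean
    monotone repolarization gives a negative value.
    """
    lo, hi = _repol_window(trace)
    seg = trace.v[lo:hi]
    if len(seg) < 2:
        raise ValueError("repolarization window is empty")
    return float(np.max(np.diff(seg)) / trace.dt_ms)


def detect_ead(trace: APTrace) -> bool:
    """True iff dV/dt > +0.01 mV/ms for >= 2 consecutive samples during
    repolarization."""
    lo, hi = _repol_window(trace)
    seg = trace.v[lo:hi]
    if len(seg) < 2:
        return False
    pos = (np.diff(seg) / trace.dt_ms) > EAD_SLOPE_THRESHOLD
    run = 0
    for flag in pos:
        run = run + 1 if flag else 0
        if run >= EAD_MIN_CONSECUTIVE:
            return True
    return False


def biomarkers(trace: APTrace) -> APBiomarkers:
    """All biomarkers of one beat."""
    _, _, resting_v, peak_v = _upstroke(trace)
    apd90, dnr90 = apd_flagged(trace, 0.9)
    apd50, _ = apd_flagged(trace, 0.5)
    return APBiomarkers(
        apd90=apd90,
        apd50=min(apd50, apd90),
        peak_v=peak_v,
        resting_v=resting_v,
        max_repol_slope=max_repol_slope(trace),
        ead=detect_ead(trace),
        did_not_repolarize=dnr90,
    )


#: Default beat-selection window: the last 250 beats of the 1000-beat run.
DEFAULT_SELECTION_WINDOW = (751, 1000)


def selection_window_beats(window: tuple[int, int] = DEFAULT_SELECTION_WINDOW) -> int:
    """Number of candidate beats in a selection window (inclusive bounds)."""
    return window[1] - window[0] + 1


def select_beat(series, window: tuple[int, int] = DEFAULT_SELECTION_WINDOW) -> APTrace:
    """Pick the machine-learning input beat from a paced run.

    Among beats with 1-based index in ``[window[0], window[1]]`` (the last
    stretch of the pacing protocol, past the transient), returns the beat
    whose repolarization-phase slope is maximal — the most-positive-slope
    reading, which captures the beat with the most pronounced EAD when one
    occurs.  Ties break toward the latest beat.
    """
    lo, hi = window
    n = series.n_beats
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid beat window {window}")
    if hi > n:
        raise ValueError(f"window {window} exceeds available beats ({n})")
    best_idx = None
    best_slope = -np.inf
    for b in range(lo, hi + 1):
        trace = series.trace(b)
        slope = max_repol_slope(trace)
        if slope >= best_slope:  # >= implements latest-beat tie-break
            best_slope = slope
            best_idx = b
    return series.trace(best_idx)
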