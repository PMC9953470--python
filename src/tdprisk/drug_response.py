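"""Dose-response ingestion, Hill-curve fitting and bootstrap uncertainty.

The CiPA in-vitro assay reports, per drug and per ion channel, the fraction
of current blocked at a handful of concentrations (several patch-clamp
replicates each).  This module fits the Hill equation

    block(D) = 1 / (1 + (IC50 / D)^h)

to those points and resamples them (nonparametric bootstrap, refit, central
95% trim on log10 IC50) to produce ``B`` plausible (IC50, h) pairs per
drug-channel pair, quantifying experimental uncertainty.  Downstream, each
sampled pair scales one channel conductance in the cell model.

IC50 = +inf is the sentinel for "no measurable block".
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: The seven CiPA ion channels, canonical order.
CHANNELS = ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

RISK_LABELS = ("high", "intermediate", "low")

#: Block values above this are taken to be on the percent (0-100) scale.
PERCENT_SCALE_THRESHOLD = 1.5

HILL_MAX = 10.0


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters for one drug-channel pair.

    ic50 in µM (may be ``inf`` meaning no block); hill dimensionless > 0.
    """

    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.ic50 > 0):
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if not (0 < self.hill <= HILL_MAX) and not math.isinf(self.ic50):
            raise ValueError(f"hill must be in (0, {HILL_MAX}], got {self.hill}")

    @property
    def no_block(self) -> bool:
        return math.isinf(self.ic50)


#: Sentinel for drug-channel pairs with no measurable block.
NO_BLOCK = HillParams(ic50=math.inf, hill=1.0)


@dataclass(frozen=True)
class DoseResponseMeasurement:
    """One replicate: fraction of channel current blocked at one concentration."""

    drug_id: str
    channel: str
    concentration: float  # µM, > 0
    block_fraction: float  # clamped to [0, 1]

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not (self.concentration > 0):
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        bf = self.block_fraction
        if bf < 0.0 or bf > 1.0:
            if bf < -0.05 or bf > 1.05:
                warnings.warn(
                    f"block_fraction {bf:.4g} for {self.drug_id}/{self.channel} "
                    "outside [0,1]; clamping",
                    stacklevel=2,
                )
            object.__setattr__(self, "block_fraction", min(1.0, max(0.0, bf)))


@dataclass
class DoseResponsePanel:
    """A collection of measurements plus per-drug Cmax and TdP risk label."""

    measurements: list[DoseResponseMeasurement]
    cmax: dict[str, float]  # drug_id -> peak serum concentration, µM
    risk_label: dict[str, str]  # drug_id -> high | intermediate | low

    def __post_init__(self) -> None:
        for drug, c in self.cmax.items():
            if not c > 0:
                raise ValueError(f"Cmax for {drug} must be positive, got {c}")
        for drug, lab in self.risk_label.items():
            if lab not in RISK_LABELS:
                raise ValueError(f"risk label for {drug} must be one of {RISK_LABELS}, got {lab!r}")
        for m in self.measurements:
            if m.drug_id not in self.cmax:
                raise ValueError(f"drug {m.drug_id!r} has measurements but no Cmax")
            if m.drug_id not in self.risk_label:
                raise ValueError(f"drug {m.drug_id!r} has measurements but no risk label")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.cmax)

    def pair(self, drug_id: str, channel: str) -> list[DoseResponseMeasurement]:
        """All replicates for one drug-channel pair."""
        return [m for m in self.measurements if m.drug_id == drug_id and m.channel == channel]

    def channels_measured(self, drug_id: str) -> list[str]:
        seen = {m.channel for m in self.measurements if m.drug_id == drug_id}
        return [c for c in CHANNELS if c in seen]


@dataclass
class HillSampleSet:
    """Bootstrap samples of Hill parameters for one drug-channel pair."""

    drug_id: str
    channel: str
    samples: list[HillParams]
    rng_seed: int

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Hill curve
# ---------------------------------------------------------------------------

def hill_block(concentration: float | np.ndarray, params: HillParams) -> float | np.ndarray:
    """Fraction of channel current blocked at drug concentration D (µM).

    block = 1 / (1 + (IC50/D)^h); 0.5 at D == IC50, 0 for the no-block
    sentinel, monotonically increasing in D.
    """
    d = np.asarray(concentration, dtype=float)
    if np.any(d <= 0):
        raise ValueError("concentration must be positive")
    if params.no_block:
        out = np.zeros_like(d)
        return float(out) if np.isscalar(concentration) else out
    # computed in log space for numeric range safety at extreme D/IC50 ratios
    ratio = np.exp(params.hill * (np.log(params.ic50) - np.log(d)))
    out = 1.0 / (1.0 + ratio)
    return float(out) if np.isscalar(concentration) else out


def conductance_scale(concentration: float, params: HillParams) -> float:
    """Multiplier on channel conductance under drug: 1 - hill_block.

    1.0 at concentration 0 (drug-free), 0.5 at D == IC50, decreasing in D.
    """
    if concentration == 0:
        return 1.0
    return 1.0 - float(hill_block(concentration, params))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_fittable(conc: np.ndarray, block: np.ndarray) -> None:
    if len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 distinct concentrations to fit a Hill curve")


def fit_hill(points: Sequence[DoseResponseMeasurement]) -> HillParams:
    """Least-squares Hill fit over (log10 IC50, h), h constrained to (0, 10].

    All-zero block at every concentration returns the no-block sentinel.
    Multistart (3 starting IC50 guesses) guards against local minima; ties
    broken by lowest residual, then lowest hill.
    """
    conc = np.array([m.concentration for m in points], dtype=float)
    block = np.array([m.block_fraction for m in points], dtype=float)
    _check_fittable(conc, block)
    if np.all(block == 0.0):
        return NO_BLOCK
    return _fit_hill_arrays(conc, block)


def _fit_hill_arrays(conc: np.ndarray, block: np.ndarray) -> HillParams:
    logc = np.log10(conc)

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_ic50, h = theta
        pred = 1.0 / (1.0 + 10.0 ** (h * (log_ic50 - logc)))
        return pred - block

    # start IC50 near the data range: below, inside, above
    starts = [logc.min() - 1.0, np.median(logc), logc.max() + 1.0]
    best: tuple[float, float, np.ndarray] | None = None
    for s in starts:
        sol = least_squares(
            residuals,
            x0=np.array([s, 1.0]),
            bounds=([-12.0, 1e-3], [12.0, HILL_MAX]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        cost = float(np.sum(sol.fun**2))
        key = (round(cost, 12), sol.x[1])
        if best is None or key < (round(best[0], 12), best[1]):
            best = (cost, sol.x[1], sol.x)
    assert best is not None
    log_ic50, h = best[2]
    return HillParams(ic50=float(10.0**log_ic50), hill=float(h))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_hill(
    points: Sequence[DoseResponseMeasurement],
    B: int = 2000,
    seed: int = 0,
    trim_quantile: float = 0.95,
) -> HillSampleSet:
    """Nonparametric bootstrap of the Hill fit.

    Replicates are resampled with replacement within each concentration and
    refit until ``B`` fits are accepted; fits whose log10(IC50) falls outside
    the central ``trim_quantile`` interval of the accepted set are then
    replaced by redraws (with replacement) from the retained fits, so exactly
    ``B`` samples remain, all inside the central 95% envelope.  If every
    concentration has a single replicate a residual (parametric) bootstrap is
    used instead and a warning is logged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pts = list(points)
    conc = np.array([m.concentration for m in pts], dtype=float)
    block = np.array([m.block_fraction for m in pts], dtype=float)
    _check_fittable(conc, block)
    drug_id, channel = pts[0].drug_id, pts[0].channel

    rng = np.random.default_rng(seed)

    if np.all(block == 0.0):
        return HillSampleSet(drug_id, channel, [NO_BLOCK] * B, seed)

    point_fit = _fit_hill_arrays(conc, block)

    groups: dict[float, np.ndarray] = {
        c: np.flatnonzero(conc == c) for c in np.unique(conc)
    }
    residual_mode = all(len(ix) < 2 for ix in groups.values())
    # resampling identical replicates cannot change the fit: short-circuit
    if not residual_mode and all(np.ptp(block[ix]) == 0.0 for ix in groups.values()):
        return HillSampleSet(drug_id, channel, [point_fit] * B, seed)
    if residual_mode:
        logger.warning(
            "bootstrap_hill(%s/%s): <2 replicates at every concentration; "
            "falling back to residual bootstrap", drug_id, channel,
        )
        fitted = np.clip(
            np.asarray(hill_block(conc, point_fit)) if not point_fit.no_block
            else np.zeros_like(conc), 0.0, 1.0,
        )
        resid = block - fitted

    fits: list[HillParams] = []
    max_tries = 50 * B
    tries = 0
    while len(fits) < B and tries < max_tries:
        tries += 1
        if residual_mode:
            b = np.clip(fitted + rng.choice(resid, size=len(resid), replace=True), 0.0, 1.0)
            c = conc
        else:
            idx = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True) for ix in groups.values()]
            )
            c, b = conc[idx], block[idx]
        if np.all(b == 0.0):
            fits.append(NO_BLOCK)
            continue
        try:
            fits.append(_fit_hill_arrays(c, b))
        except ValueError:
            continue
    if len(fits) < B:
        raise RuntimeError(f"bootstrap_hill: only {len(fits)}/{B} fits converged")

    # central-95% trim on log10(IC50); redraw from the retained fits to keep B
    log_ic50 = np.array([math.log10(f.ic50) if not f.no_block else math.inf for f in fits])
    finite = np.isfinite(log_ic50)
    if finite.sum() > 0 and finite.sum() < len(fits):
        # mixed no-block / block resamples: trim only among the finite ones
        lo, hi = np.quantile(log_ic50[finite], [(1 - trim_quantile) / 2, 1 - (1 - trim_quantile) / 2])
        keep = [f for f, l in zip(fits, log_ic50) if (not np.isfinite(l)) or lo <= l <= hi]
    elif finite.all():
        lo, hi = np.quantile(log_ic50, [(1 - trim_quantile) / 2, 1 - (1 - trim_quantile) / 2])
        keep = [f for f, l in zip(fits, log_ic50) if lo <= l <= hi]
    else:
        keep = fits
    if len(keep) < len(fits):
        refill = rng.integers(0, len(keep), size=len(fits) - len(keep))
        samples = keep + [keep[i] for i in refill]
    else:
        samples = keep
    assert len(samples) == B
    return HillSampleSet(drug_id, channel, samples, seed)


def bootstrap_panel(
    panel: DoseResponsePanel, B: int = 2000, seed: int = 0
) -> dict[tuple[str, str], HillSampleSet]:
    """Bootstrap every measured drug-channel pair of a panel.

    Per-pair seeds are derived deterministically from ``seed`` so the result
    does not depend on iteration order.
    """
    out: dict[tuple[str, str], HillSampleSet] = {}
    for drug in panel.drugs:
        for ch in panel.channels_measured(drug):
            sub_seed = int(np.random.default_rng([seed, _stable_hash(drug), _stable_hash(ch)])
                           .integers(0, 2**31 - 1))
            out[(drug, ch)] = bootstrap_hill(panel.pair(drug, ch), B=B, seed=sub_seed)
    return out


def _stable_hash(s: str) -> int:
    # process-independent (hash() is salted)
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# I/O — CiPA-repository CSV dialect
# ---------------------------------------------------------------------------

_DOSE_COLS = ("drug", "channel", "conc_uM", "block")
_META_COLS = ("drug", "cmax_uM", "risk")


def read_cipa_csv(dose_path, meta_path) -> DoseResponsePanel:
    """Read a dose-response CSV and drug-metadata CSV into a panel.

    Dose CSV columns: drug, channel, conc_uM, block (replicates as repeated
    rows).  Metadata CSV columns: drug, cmax_uM, risk.  Block columns on the
    percent (0-100) scale are auto-detected (any value > 1.5) and rescaled
    to fractions with a logged notice.
    """
    dose = pd.read_csv(dose_path)
    meta = pd.read_csv(meta_path)
    for col in _DOSE_COLS:
        if col not in dose.columns:
            raise ValueError(f"dose CSV missing required column {col!r}")
    for col in _META_COLS:
        if col not in meta.columns:
            raise ValueError(f"metadata CSV missing required column {col!r}")

    block = pd.to_numeric(dose["block"], errors="coerce")
    conc = pd.to_numeric(dose["conc_uM"], errors="coerce")
    bad = conc.isna() | block.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"dose CSV row {row}: non-numeric conc_uM/block "
                         f"({dose.iloc[row].to_dict()})")
    if (block > PERCENT_SCALE_THRESHOLD).any():
        logger.info("block column appears percent-scaled (max %.3g); dividing by 100",
                    block.max())
        block = block / 100.0

    cmax = {str(r.drug): float(r.cmax_uM) for r in meta.itertuples()}
    risk = {str(r.drug): str(r.risk) for r in meta.itertuples()}
    for drug in dose["drug"].astype(str).unique():
        if drug not in cmax:
            raise ValueError(f"drug {drug!r} present in dose CSV but missing from metadata")

    measurements = []
    for i, r in enumerate(dose.itertuples()):
        ch = str(r.channel)
        if ch not in CHANNELS:
            raise ValueError(f"dose CSV row {i}: unknown channel {ch!r}")
        measurements.append(
            DoseResponseMeasurement(str(r.drug), ch, float(conc.iloc[i]), float(block.iloc[i]))
        )
    return DoseResponsePanel(measurements, cmax, risk)


def write_panel(panel: DoseResponsePanel, dose_path, meta_path) -> None:
    """Inverse of :func:`read_cipa_csv` (fraction-scale block column)."""
    pd.DataFrame(
        [(m.drug_id, m.channel, m.concentration, m.block_fraction) for m in panel.measurements],
        columns=list(_DOSE_COLS),
    ).to_csv(dose_path, index=False)
    pd.DataFrame(
        [(d, panel.cmax[d], panel.risk_label[d]) for d in panel.drugs],
        columns=list(_META_COLS),
    ).to_csv(meta_path, index=False)


def hill_samples_to_frame(samples: Mapping[tuple[str, str], HillSampleSet]) -> pd.DataFrame:
    """Tabular container: drug, channel, sample_index, ic50, hill."""
    rows = []
    for (drug, ch), ss in samples.items():
        for i, p in enumerate(ss.samples):
            rows.append((drug, ch, i, p.ic50, p.hill))
    return pd.DataFrame(rows, columns=["drug", "channel", "sample_index", "ic50", "hill"])


def hill_samples_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], HillSampleSet]:
    out: dict[tuple[str, str], HillSampleSet] = {}
    for (drug, ch), grp in df.groupby(["drug", "channel"], sort=True):
        grp = grp.sort_values("sample_index")
        samples = [
            NO_BLOCK if np.isinf(ic50) else HillParams(float(ic50), float(h))
            for ic50, h in zip(grp["ic50"], grp["hill"])
        ]
        out[(str(drug), str(ch))] = HillSampleSet(str(drug), str(ch), samples, rng_seed=-1)
    return out
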