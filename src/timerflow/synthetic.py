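"""Synthetic Fluorescent Timer flow-cytometry data from a kinetic model.

The generator exists so that every pipeline stage can be exercised and
verified without instrument data. It simulates the minimal physics of a
blue-to-red maturing Timer protein (Fast-FT-like) under continuous
production:

    dB/dt = p - (m + d) * B        B(0) = 0
    dR/dt = m * B - d * R          R(0) = 0

where ``B`` is the immature (blue-fluorescent) amount, ``R`` the mature
(red-fluorescent) amount, ``p`` the production rate, ``m = ln2 / t_half,mat``
the maturation rate (default half-time 4 h) and ``d = ln2 / t_half,deg`` a
shared degradation rate (default half-time 24 h; ``inf`` disables
degradation). Closed forms:

    B(t) = p/(m+d) * (1 - exp(-(m+d) t))
    R(t) = m p/(m+d) * [ (1 - exp(-d t))/d  -  exp(-d t)(1 - exp(-m t))/m ]

with the ``d -> 0`` limit ``(1 - exp(-d t))/d -> t``. For a pulse (bolus
``B(0) = B0``, no production) the immature fraction is
``B/(B+R) = exp(-m t)`` regardless of ``d`` — shared degradation cancels —
which is what the maturation-half-time fit exploits.

Measurement model: per-cell amounts are scaled by channel gains,
multiplied by lognormal noise (given CV), and *every* cell — Timer-on or
not — receives additive lognormal autofluorescence in both channels. The
negative control is the autofluorescence-only draw. A forward-scatter
channel is included so size-related QC summaries have something to chew on.

All draws are made with numpy's PCG64 generator from explicit seeds, so a
dataset is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_manifest import CellMatrix, SampleManifest, build_manifest

BLUE_CHANNEL = "Timer_Blue"
RED_CHANNEL = "Timer_Red"
FSC_CHANNEL = "FSC"

NEGATIVE_CONTROL_NAME = "negative_control"
TRUTH_SUBDIR = "truth"


@dataclass(frozen=True)
class KineticsConfig:
    """Timer protein kinetics. Half-times in hours; production in
    molecules/hour per cell."""

    maturation_halftime: float = 4.0
    degradation_halftime: float = 24.0
    production_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.maturation_halftime > 0 and np.isfinite(self.maturation_halftime)):
            raise ConfigurationError("maturation_halftime must be finite and > 0")
        if not self.degradation_halftime > 0:
            raise ConfigurationError("degradation_halftime must be > 0 (inf allowed)")
        if self.production_rate < 0:
            raise ConfigurationError("production_rate must be >= 0")

    @property
    def maturation_rate(self) -> float:
        return math.log(2.0) / self.maturation_halftime

    @property
    def degradation_rate(self) -> float:
        return 0.0 if math.isinf(self.degradation_halftime) else math.log(2.0) / self.degradation_halftime


@dataclass(frozen=True)
class MeasurementConfig:
    """Acquisition model: channel gains (fluorescence units per molecule),
    lognormal autofluorescence background (log10 units), multiplicative
    signal noise (CV), cells per sample, and the seed."""

    blue_gain: float = 1.0
    red_gain: float = 1.0
    autofluorescence_mu_blue: float = 2.0
    autofluorescence_mu_red: float = 2.0
    autofluorescence_sigma: float = 0.2
    noise_cv: float = 0.3
    n_cells: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blue_gain <= 0 or self.red_gain <= 0:
            raise ConfigurationError("gains must be > 0")
        if self.autofluorescence_sigma <= 0:
            raise ConfigurationError("autofluorescence_sigma must be > 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _rel_expm1(rate: float, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-rate t)) / rate, with the rate -> 0 limit t."""
    if rate == 0.0:
        return t.copy()
    return -np.expm1(-rate * t) / rate


def kinetic_amounts(config: KineticsConfig, t) -> tuple[np.ndarray, np.ndarray]:
    """Immature and mature amounts at time(s) ``t`` hours after onset of
    constant production, from the closed-form solution above."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("t must be >= 0")
    m = config.maturation_rate
    d = config.degradation_rate
    a = m + d
    p = config.production_rate
    B = p / a * (-np.expm1(-a * t))
    R = m * p / a * (_rel_expm1(d, t) - np.exp(-d * t) * (-np.expm1(-m * t)) / m)
    return B, R


def pulse_amounts(config: KineticsConfig, t, initial_amount: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-chase: a bolus of immature protein at t = 0, production off.

    ``B(t) = B0 exp(-(m+d) t)``, ``R(t) = B0 exp(-d t)(1 - exp(-m t))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("t must be >= 0")
    m = config.maturation_rate
    d = config.degradation_rate
    B = initial_amount * np.exp(-(m + d) * t)
    R = initial_amount * np.exp(-d * t) * (-np.expm1(-m * t))
    return B, R


def fit_maturation_halftime(t, blue_amounts, red_amounts) -> float:
    """Recover the maturation half-time from pulse-chase amounts by fitting
    a single exponential to the immature fraction B/(B+R).

    The fraction equals exp(-m t) independent of shared degradation, so an
    ordinary least-squares line through ln(fraction) vs t gives -m.
    """
    t = np.asarray(t, dtype=float)
    B = np.asarray(blue_amounts, dtype=float)
    R = np.asarray(red_amounts, dtype=float)
    total = B + R
    ok = (total > 0) & (B > 0)
    if ok.sum() < 2:
        raise ConfigurationError("need at least two usable time points to fit")
    frac = B[ok] / total[ok]
    slope = np.polyfit(t[ok], np.log(frac), 1)[0]
    if slope >= 0:
        raise ConfigurationError("immature fraction does not decay; cannot fit")
    return math.log(2.0) / (-slope)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, n)


def _autofluorescence(rng: np.random.Generator, mu: float, sigma: float, n: int) -> np.ndarray:
    return 10.0 ** rng.normal(mu, sigma, n)


def _fsc(rng: np.random.Generator, n: int, timer_on: np.ndarray) -> np.ndarray:
    # activated (Timer-on) cells run slightly larger, mimicking blasting
    return 10.0 ** (rng.normal(5.0, 0.1, n) + 0.05 * timer_on)


def simulate_negative_control(
    meas: MeasurementConfig, rng: np.random.Generator | None = None
) -> CellMatrix:
    """Timer-negative sample: autofluorescence only in both channels."""
    rng = np.random.default_rng(meas.seed) if rng is None else rng
    n = meas.n_cells
    off = np.zeros(n)
    blue = _autofluorescence(rng, meas.autofluorescence_mu_blue, meas.autofluorescence_sigma, n)
    red = _autofluorescence(rng, meas.autofluorescence_mu_red, meas.autofluorescence_sigma, n)
    data = pd.DataFrame({BLUE_CHANNEL: blue, RED_CHANNEL: red, FSC_CHANNEL: _fsc(rng, n, off)})
    return CellMatrix(NEGATIVE_CONTROL_NAME, data)


def simulate_sample(
    kin: KineticsConfig,
    meas: MeasurementConfig,
    timer_on_fraction: float,
    elapsed_hours: float,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    return_truth: bool = False,
):
    """One sample: a ``timer_on_fraction`` subset of cells expresses Timer,
    with per-cell onset ages uniform on [0, elapsed_hours] (continuous
    stimulation); all cells carry autofluorescence.

    Returns the :class:`CellMatrix`, or ``(CellMatrix, truth)`` where truth
    holds per-cell onset age, true amounts and the Timer-on flag.
    """
    if not 0.0 <= timer_on_fraction <= 1.0:
        raise ConfigurationError(f"timer_on_fraction must be in [0, 1], got {timer_on_fraction}")
    if elapsed_hours < 0:
        raise ConfigurationError("elapsed_hours must be >= 0")
    rng = np.random.default_rng(meas.seed) if rng is None else rng
    n = meas.n_cells
    timer_on = rng.random(n) < timer_on_fraction
    ages = rng.uniform(0.0, elapsed_hours, n) if elapsed_hours > 0 else np.zeros(n)
    B, R = kinetic_amounts(kin, ages)
    B = np.where(timer_on, B, 0.0)
    R = np.where(timer_on, R, 0.0)
    blue = B * meas.blue_gain * _lognormal_noise(rng, meas.noise_cv, n) + _autofluorescence(
        rng, meas.autofluorescence_mu_blue, meas.autofluorescence_sigma, n
    )
    red = R * meas.red_gain * _lognormal_noise(rng, meas.noise_cv, n) + _autofluorescence(
        rng, meas.autofluorescence_mu_red, meas.autofluorescence_sigma, n
    )
    data = pd.DataFrame(
        {BLUE_CHANNEL: blue, RED_CHANNEL: red, FSC_CHANNEL: _fsc(rng, n, timer_on.astype(float))}
    )
    cells = CellMatrix(sample_id, data)
    if not return_truth:
        return cells
    truth = pd.DataFrame(
        {"onset_age_h": ages, "true_blue_amount": B, "true_red_amount": R, "timer_on": timer_on}
    )
    return cells, truth


def simulate_timecourse(
    kin: KineticsConfig,
    meas: MeasurementConfig,
    timepoints: list[float],
    samples_per_timepoint: int = 3,
    out_dir: Path | str = ".",
    timer_on_fraction: float = 0.8,
) -> SampleManifest:
    """Write a full time-course dataset: one CSV per (timepoint, replicate),
    one negative-control CSV, ground-truth sidecars under ``truth/``, and a
    serialized manifest with group labels = timepoint.

    Each file gets its own generator seeded from ``(meas.seed, index)`` so
    the dataset is reproducible file-by-file and insensitive to generation
    order.
    """
    if not timepoints:
        raise ConfigurationError("timepoints must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / TRUTH_SUBDIR
    truth_dir.mkdir(exist_ok=True)

    paths: list[Path] = []
    groups: dict[str, str] = {}
    idx = 0
    for tp in timepoints:
        label = f"{tp:g}h"
        for rep in range(1, samples_per_timepoint + 1):
            sid = f"sample_{label}_r{rep}"
            rng = np.random.default_rng([meas.seed, idx])
            cells, truth = simulate_sample(
                kin, meas, timer_on_fraction, tp, rng=rng, sample_id=sid, return_truth=True
            )
            p = out_dir / f"{sid}.csv"
            cells.data.to_csv(p, index=False)
            truth.to_csv(truth_dir / f"{sid}.truth.csv", index=False)
            paths.append(p)
            groups[sid] = label
            idx += 1

    rng = np.random.default_rng([meas.seed, idx])
    neg = simulate_negative_control(meas, rng=rng)
    neg_path = out_dir / f"{NEGATIVE_CONTROL_NAME}.csv"
    neg.data.to_csv(neg_path, index=False)
    paths.append(neg_path)
    groups[NEGATIVE_CONTROL_NAME] = "control"

    return build_manifest(
        paths,
        negative_control=neg_path,
        blue_channel=BLUE_CHANNEL,
        red_channel=RED_CHANNEL,
        groups=groups,
        output_dir=out_dir,
    )
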