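"""Timer thresholding, normalization, and trigonometric transformation.

The preprocessing pipeline turns raw two-channel Fluorescent Timer data
(blue = immature chromophore, red = mature chromophore) into per-cell Timer
Angle and Timer Intensity. It runs in a fixed order:

1. **Thresholding** — per-channel gating thresholds are taken from the
   Timer-negative control, either as empirical quantiles of its raw
   fluorescence or as explicit manual values. The same thresholds gate the
   negative control (inclusive, ``<=``) and define Timer positivity in the
   samples (strict, ``>``): a cell exactly at threshold is background.
2. **Normalization parameters** — on the gated negative-control cells, the
   per-channel location is the maximum of the log10-transformed
   fluorescence and the scale is either the sample SD or the scaled MAD
   (x 1.4826, so both estimate the same sigma under normality; MAD is the
   robust default).
3. **Normalization** — each cell's log fluorescence is centred on the
   negative-control maximum and divided by the scale::

       B_norm = (B_log - max(B_log_gated_neg)) / scale(B_log_gated_neg)

   and identically for red. A value of 0 therefore means "at the top of the
   autofluorescence background". Because shifting all raw values by a
   multiplicative gain shifts the log values and the location identically
   and leaves the spread unchanged, normalized values are invariant to
   channel gain — the point of the whole exercise.
4. **Trigonometric transform** — normalized values are clamped at 0
   (expression below background carries no directional information) and
   mapped to polar coordinates::

       I     = sqrt(Bc**2 + Rc**2)
       theta = arccos(Bc / I) * 180 / pi          (degrees)

   so theta runs from 0 deg (pure blue, new expression) to 90 deg (pure
   red, aged expression). A cell at the origin (I = 0) has no defined
   direction and carries a missing angle.

Log convention: log10 with a floor (default 1 raw unit) applied before the
log, making the transform total on instrument exports that contain zeros or
small negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, MIN_GATE_SIZE
from .io_manifest import CellMatrix, SampleManifest, read_cell_matrix

logger = logging.getLogger("timerflow")

#: MAD -> SD consistency constant under normality.
MAD_CONSTANT = 1.4826

QUADRANT_NEG_NEG = "NegNeg"
QUADRANT_BLUE_ONLY = "BluePosRedNeg"
QUADRANT_DOUBLE = "BluePosRedPos"
QUADRANT_RED_ONLY = "BlueNegRedPos"
QUADRANTS = (QUADRANT_NEG_NEG, QUADRANT_BLUE_ONLY, QUADRANT_DOUBLE, QUADRANT_RED_ONLY)

#: Column order of the per-sample transformed table.
TRANSFORMED_COLUMNS = (
    "cell_id", "blue_log", "red_log", "blue_norm", "red_norm",
    "angle_deg", "intensity", "timer_positive", "quadrant",
)


# ---------------------------------------------------------------------------
# configuration / parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """How gating thresholds are obtained: quantile of the negative control
    (default q = 0.975, a conventional 2.5% autofluorescence-tail gate) or
    explicit manual values in raw units."""

    method: str = "quantile"
    quantile_q: float = 0.975
    manual_blue: float | None = None
    manual_red: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("quantile", "manual"):
            raise ConfigurationError(f"unknown threshold method {self.method!r}")
        if self.method == "quantile" and not 0.0 < self.quantile_q < 1.0:
            raise ConfigurationError(
                f"quantile_q must be in (0, 1), got {self.quantile_q}"
            )
        if self.method == "manual" and (self.manual_blue is None or self.manual_red is None):
            raise ConfigurationError(
                "manual thresholding requires both manual_blue and manual_red"
            )


@dataclass(frozen=True)
class GateThresholds:
    """Raw-unit thresholds on blue and red fluorescence."""

    blue_threshold: float
    red_threshold: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.blue_threshold) and np.isfinite(self.red_threshold)):
            raise ConfigurationError("thresholds must be finite")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel location (max of log gated-negative fluorescence) and
    scale (SD or scaled MAD of the same), plus the conventions used."""

    method: str
    log_floor: float
    blue_max_log_neg: float
    blue_scale_log_neg: float
    red_max_log_neg: float
    red_scale_log_neg: float
    n_gated_neg: int
    log_base: int = 10


@dataclass
class TransformedCells:
    """Per-cell transformed table for one sample (columns as in
    :data:`TRANSFORMED_COLUMNS`)."""

    sample_id: str
    data: pd.DataFrame = field(repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.data)


@dataclass
class TockyResult:
    """Everything a batch run produces: per-sample transformed cells, the
    thresholds and normalization parameters shared by all samples, per-sample
    counts, and the sample definition table."""

    samples: dict[str, TransformedCells]
    thresholds: GateThresholds
    params: NormalizationParams
    counts: pd.DataFrame
    sample_definition: pd.DataFrame
    normalize: bool = True


# ---------------------------------------------------------------------------
# elementwise building blocks
# ---------------------------------------------------------------------------

def log_transform(values, log_floor: float = 1.0) -> np.ndarray:
    """log10 of ``max(value, log_floor)``, elementwise.

    The floor absorbs non-positive values so the transform is total; the
    number of floored values is logged because a large count usually means
    the floor (or the export's scaling) is wrong for this instrument.
    """
    if log_floor <= 0:
        raise ConfigurationError(f"log_floor must be > 0, got {log_floor}")
    values = np.asarray(values, dtype=float)
    n_floored = int(np.sum(values < log_floor))
    if n_floored:
        logger.debug("log_transform: %d value(s) at/below floor %g", n_floored, log_floor)
    return np.log10(np.maximum(values, log_floor))


def compute_gate_thresholds(
    neg: CellMatrix,
    spec: ThresholdSpec,
    blue_channel: str,
    red_channel: str,
) -> GateThresholds:
    """Thresholds from the negative control: per-channel empirical quantile
    (linear interpolation between order statistics) or the manual values."""
    if spec.method == "manual":
        return GateThresholds(float(spec.manual_blue), float(spec.manual_red))
    if neg.n_cells < MIN_GATE_SIZE:
        raise DataError(
            f"negative control has {neg.n_cells} cells; need >= {MIN_GATE_SIZE}"
        )
    blue = float(np.quantile(neg.channel(blue_channel), spec.quantile_q))
    red = float(np.quantile(neg.channel(red_channel), spec.quantile_q))
    return GateThresholds(blue, red)


def gate_negative_cells(
    neg: CellMatrix,
    thr: GateThresholds,
    blue_channel: str,
    red_channel: str,
    min_cells: int = MIN_GATE_SIZE,
) -> CellMatrix:
    """Negative-control cells at or below both thresholds (inclusive),
    row order preserved. Fails when fewer than ``min_cells`` survive —
    normalization statistics on a handful of cells are noise."""
    blue = neg.channel(blue_channel)
    red = neg.channel(red_channel)
    keep = (blue <= thr.blue_threshold) & (red <= thr.red_threshold)
    n_kept = int(keep.sum())
    logger.info("gated negative control: %d / %d cells retained", n_kept, neg.n_cells)
    if n_kept < min_cells:
        raise DataError(
            f"gated negative control has {n_kept} cells (of {neg.n_cells}); "
            f"need >= {min_cells}"
        )
    return CellMatrix(neg.sample_id, neg.data.loc[keep].reset_index(drop=True))


def _scale(log_values: np.ndarray, method: str) -> float:
    if method == "SD":
        return float(np.std(log_values, ddof=1))
    med = np.median(log_values)
    return float(np.median(np.abs(log_values - med)) * MAD_CONSTANT)


def compute_normalization_params(
    gated_neg: CellMatrix,
    blue_channel: str,
    red_channel: str,
    method: str = "MAD",
    log_floor: float = 1.0,
) -> NormalizationParams:
    """Location and scale of the log gated-negative fluorescence per channel.

    Location is the maximum; scale is the n-1 sample SD or the scaled MAD.
    A zero scale means the control is degenerate (all cells identical in a
    channel) and is a hard error — silently dividing by ~0 would blow every
    normalized value up to garbage.
    """
    if method not in ("MAD", "SD"):
        raise ConfigurationError(f"normalization method must be MAD or SD, got {method!r}")
    if gated_neg.n_cells < 2:
        raise DataError("gated negative control too small to estimate a scale")
    blue_log = log_transform(gated_neg.channel(blue_channel), log_floor)
    red_log = log_transform(gated_neg.channel(red_channel), log_floor)
    params = NormalizationParams(
        method=method,
        log_floor=log_floor,
        blue_max_log_neg=float(blue_log.max()),
        blue_scale_log_neg=_scale(blue_log, method),
        red_max_log_neg=float(red_log.max()),
        red_scale_log_neg=_scale(red_log, method),
        n_gated_neg=gated_neg.n_cells,
    )
    if params.blue_scale_log_neg <= 0 or params.red_scale_log_neg <= 0:
        raise DataError(
            "degenerate negative control: zero spread in log fluorescence "
            f"(blue scale {params.blue_scale_log_neg}, red scale {params.red_scale_log_neg})"
        )
    return params


def normalize_channel(log_values, location: float, scale: float) -> np.ndarray:
    """``(x - location) / scale`` elementwise; no clamping here — negative
    values (below background) are meaningful for QC and are only floored at
    the trigonometric step."""
    if scale <= 0:
        raise ConfigurationError(f"scale must be > 0, got {scale}")
    return (np.asarray(log_values, dtype=float) - location) / scale


def classify_timer_positive(blue_raw, red_raw, thr: GateThresholds) -> np.ndarray:
    """True iff a cell exceeds the blue OR the red threshold (strict)."""
    blue_raw = np.asarray(blue_raw, dtype=float)
    red_raw = np.asarray(red_raw, dtype=float)
    return (blue_raw > thr.blue_threshold) | (red_raw > thr.red_threshold)


def quadrant_classify(blue_raw, red_raw, thr: GateThresholds) -> np.ndarray:
    """Quadrant label per cell from raw blue/red vs the thresholds.

    Exactly one label per cell; cells exactly at threshold count as negative,
    consistent with strict Timer positivity.
    """
    blue_pos = np.asarray(blue_raw, dtype=float) > thr.blue_threshold
    red_pos = np.asarray(red_raw, dtype=float) > thr.red_threshold
    out = np.where(
        blue_pos & red_pos, QUADRANT_DOUBLE,
        np.where(blue_pos, QUADRANT_BLUE_ONLY,
                 np.where(red_pos, QUADRANT_RED_ONLY, QUADRANT_NEG_NEG)),
    )
    return out


def trig_transform(blue_norm, red_norm) -> tuple[np.ndarray, np.ndarray]:
    """Polar transform of normalized blue/red: returns (angle_deg, intensity).

    Normalized values are clamped at 0 first, so the arccos argument is in
    [0, 1] and the angle is guaranteed in [0, 90] degrees. Cells at the
    origin get intensity 0 and a missing (NaN) angle.
    """
    b = np.maximum(np.asarray(blue_norm, dtype=float), 0.0)
    r = np.maximum(np.asarray(red_norm, dtype=float), 0.0)
    intensity = np.hypot(b, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(intensity > 0, b / np.where(intensity > 0, intensity, 1.0), np.nan)
    angle = np.degrees(np.arccos(np.clip(ratio, 0.0, 1.0)))
    angle = np.where(intensity > 0, angle, np.nan)
    return angle, intensity


# ---------------------------------------------------------------------------
# per-sample and batch orchestration
# ---------------------------------------------------------------------------

def transform_sample(
    sample: CellMatrix,
    thr: GateThresholds,
    params: NormalizationParams,
    blue_channel: str,
    red_channel: str,
    normalize: bool = True,
) -> TransformedCells:
    """Full per-sample transform.

    With ``normalize=False`` the log values are only centred on the
    negative-control maximum (scale 1) — the "non-normalized" mode used to
    demonstrate what acquisition bias does to the angle. Angle and intensity
    are computed for Timer-positive cells only; background cells carry
    missing values so they can never leak into downstream angle statistics.
    """
    blue_raw = sample.channel(blue_channel)
    red_raw = sample.channel(red_channel)
    blue_log = log_transform(blue_raw, params.log_floor)
    red_log = log_transform(red_raw, params.log_floor)
    if normalize:
        blue_norm = normalize_channel(blue_log, params.blue_max_log_neg, params.blue_scale_log_neg)
        red_norm = normalize_channel(red_log, params.red_max_log_neg, params.red_scale_log_neg)
    else:
        blue_norm = blue_log - params.blue_max_log_neg
        red_norm = red_log - params.red_max_log_neg
    positive = classify_timer_positive(blue_raw, red_raw, thr)
    quadrant = quadrant_classify(blue_raw, red_raw, thr)
    angle, intensity = trig_transform(blue_norm, red_norm)
    angle = np.where(positive, angle, np.nan)
    intensity = np.where(positive, intensity, np.nan)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(sample.n_cells),
            "blue_log": blue_log,
            "red_log": red_log,
            "blue_norm": blue_norm,
            "red_norm": red_norm,
            "angle_deg": angle,
            "intensity": intensity,
            "timer_positive": positive,
            "quadrant": quadrant,
        },
        columns=list(TRANSFORMED_COLUMNS),
    )
    return TransformedCells(sample.sample_id, table)


def _count_row(sample_id: str, group: str, t: TransformedCells) -> dict:
    q = t.data["quadrant"].value_counts()
    row = {
        "sample_id": sample_id,
        "group": group,
        "n_total": t.n_cells,
        "n_timer_positive": int(t.data["timer_positive"].sum()),
    }
    for label in QUADRANTS:
        row[f"n_{label}"] = int(q.get(label, 0))
    return row


def apply_blue_multiplier(data: CellMatrix, k: float, blue_channel: str) -> CellMatrix:
    """Multiply the blue channel by ``k``, leaving every other channel
    untouched — the acquisition-gain bias experiment."""
    if k <= 0:
        raise ConfigurationError(f"multiplier must be > 0, got {k}")
    out = data.data.copy()
    out[blue_channel] = out[blue_channel] * k
    return CellMatrix(data.sample_id, out)


def timer_transform_batch(
    manifest: SampleManifest,
    spec: ThresholdSpec | None = None,
    method: str = "MAD",
    normalize: bool = True,
    log_floor: float = 1.0,
    output_dir: Path | str | None = None,
) -> TockyResult:
    """Run the full pipeline over a manifest.

    Fixed order: thresholds from the negative control, gate the negative
    control, normalization parameters from the gated cells, then transform
    every sample *and* the control with the same thresholds and parameters.
    Any stage's fatal error aborts the whole batch naming the sample.
    If ``output_dir`` is given, per-sample transformed tables, the
    parameters file, the counts table and the sample definition are written
    there as CSV (floats at 6 significant digits).
    """
    spec = spec or ThresholdSpec()
    blue, red = manifest.blue_channel, manifest.red_channel
    neg_entry = manifest.negative_control
    neg = read_cell_matrix(neg_entry, manifest.common_variables)
    thr = compute_gate_thresholds(neg, spec, blue, red)
    gated = gate_negative_cells(neg, thr, blue, red)
    params = compute_normalization_params(gated, blue, red, method=method, log_floor=log_floor)

    samples: dict[str, TransformedCells] = {}
    count_rows = []
    for entry in manifest.entries:
        try:
            mat = neg if entry is neg_entry else read_cell_matrix(entry, manifest.common_variables)
            t = transform_sample(mat, thr, params, blue, red, normalize=normalize)
        except (DataError, ConfigurationError) as exc:
            raise type(exc)(f"sample {entry.sample_id!r}: {exc}") from exc
        samples[entry.sample_id] = t
        count_rows.append(_count_row(entry.sample_id, entry.group, t))

    counts = pd.DataFrame(count_rows)
    sample_definition = pd.DataFrame(
        [
            {"sample_id": e.sample_id, "path": str(e.path), "role": e.role, "group": e.group}
            for e in manifest.entries
        ]
    )
    result = TockyResult(
        samples=samples,
        thresholds=thr,
        params=params,
        counts=counts,
        sample_definition=sample_definition,
        normalize=normalize,
    )
    if output_dir is not None:
        write_result(result, output_dir)
    return result


PARAMETERS_FILE = "normalization_parameters.csv"
COUNTS_FILE = "cell_counts.csv"
SAMPLE_DEFINITION_OUT = "sample_definition.csv"
FLOAT_FORMAT = "%.6g"


def write_result(result: TockyResult, directory: Path | str) -> list[Path]:
    """Write all batch outputs as CSV; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, t in result.samples.items():
        p = directory / f"{sid}_transformed.csv"
        t.data.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        written.append(p)
    thr, prm = result.thresholds, result.params
    params_table = pd.DataFrame(
        [
            {
                "blue_threshold": thr.blue_threshold,
                "red_threshold": thr.red_threshold,
                "blue_max_log_neg": prm.blue_max_log_neg,
                "blue_scale_log_neg": prm.blue_scale_log_neg,
                "red_max_log_neg": prm.red_max_log_neg,
                "red_scale_log_neg": prm.red_scale_log_neg,
                "method": prm.method,
                "log_floor": prm.log_floor,
                "n_gated_neg": prm.n_gated_neg,
                "normalize": result.normalize,
            }
        ]
    )
    p = directory / PARAMETERS_FILE
    params_table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
    written.append(p)
    p = directory / COUNTS_FILE
    result.counts.to_csv(p, index=False)
    written.append(p)
    p = directory / SAMPLE_DEFINITION_OUT
    result.sample_definition.to_csv(p, index=False)
    written.append(p)
    return written


def load_result(directory: Path | str) -> TockyResult:
    """Reload a :class:`TockyResult` from a directory written by
    :func:`write_result` (used by the qc subcommand)."""
    directory = Path(directory)
    params_table = pd.read_csv(directory / PARAMETERS_FILE)
    row = params_table.iloc[0]
    thr = GateThresholds(float(row.blue_threshold), float(row.red_threshold))
    prm = NormalizationParams(
        method=str(row.method),
        log_floor=float(row.log_floor),
        blue_max_log_neg=float(row.blue_max_log_neg),
        blue_scale_log_neg=float(row.blue_scale_log_neg),
        red_max_log_neg=float(row.red_max_log_neg),
        red_scale_log_neg=float(row.red_scale_log_neg),
        n_gated_neg=int(row.n_gated_neg),
    )
    counts = pd.read_csv(directory / COUNTS_FILE).fillna({"group": ""})
    counts["group"] = counts["group"].astype(str)
    defn = pd.read_csv(directory / SAMPLE_DEFINITION_OUT).fillna({"group": ""})
    defn["group"] = defn["group"].astype(str)
    samples = {}
    for sid in defn["sample_id"]:
        table = pd.read_csv(directory / f"{sid}_transformed.csv")
        samples[str(sid)] = TransformedCells(str(sid), table)
    return TockyResult(
        samples=samples,
        thresholds=thr,
        params=prm,
        counts=counts,
        sample_definition=defn,
        normalize=bool(row.normalize),
    )
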