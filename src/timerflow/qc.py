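"""Per-sample summaries and quality-control plot data.

Summaries cover what a bench scientist checks first after a run: total and
Timer-positive counts, quadrant fractions, mean fluorescence intensities
(MFI) per channel, mean forward scatter when present, and mean Timer Angle
and Intensity over the Timer-positive cells.

Figures are deliberately a thin rendering layer: every plotted point is
also written to a plot-data CSV that is a pure projection of the transform
output (no recomputation), so tests assert on data instead of pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io_manifest import CellMatrix, SampleManifest, read_cell_matrix
from .preprocess import QUADRANTS, TockyResult, TransformedCells, log_transform

logger = logging.getLogger("timerflow")

PLOT_MODES = ("timer_fluorescence", "normalized_timer_fluorescence", "angle_intensity")


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    group: str
    n_total: int
    n_timer_positive: int
    quadrant_fractions: dict
    mfi_blue: float
    mfi_red: float
    mean_fsc: float | None
    mean_angle: float | None
    mean_intensity: float | None


def summarize_sample(
    t: TransformedCells,
    raw: CellMatrix,
    blue_channel: str,
    red_channel: str,
    fsc_channel: str | None = None,
    group: str = "",
    geometric: bool = False,
) -> SampleSummary:
    """Summary statistics for one sample.

    MFIs are arithmetic means of raw values (geometric means on request);
    angle/intensity means are over Timer-positive cells only, and are
    missing when there are none. Quadrant fractions are over all cells and
    sum to 1.
    """
    if t.n_cells != raw.n_cells:
        raise DataError(
            f"{t.sample_id}: transformed table ({t.n_cells} cells) is not "
            f"row-aligned with raw data ({raw.n_cells} cells)"
        )

    def _mfi(values: np.ndarray) -> float:
        if geometric:
            return float(10.0 ** np.mean(log_transform(values)))
        return float(np.mean(values))

    n = t.n_cells
    qcounts = t.data["quadrant"].value_counts()
    fractions = {label: float(qcounts.get(label, 0)) / n for label in QUADRANTS}
    pos = t.data["timer_positive"].to_numpy(dtype=bool)
    n_pos = int(pos.sum())
    if n_pos:
        mean_angle = float(np.nanmean(t.data.loc[pos, "angle_deg"]))
        mean_intensity = float(np.nanmean(t.data.loc[pos, "intensity"]))
    else:
        mean_angle = mean_intensity = None
    mean_fsc = (
        float(np.mean(raw.channel(fsc_channel)))
        if fsc_channel and fsc_channel in raw.channels
        else None
    )
    return SampleSummary(
        sample_id=t.sample_id,
        group=group,
        n_total=n,
        n_timer_positive=n_pos,
        quadrant_fractions=fractions,
        mfi_blue=_mfi(raw.channel(blue_channel)),
        mfi_red=_mfi(raw.channel(red_channel)),
        mean_fsc=mean_fsc,
        mean_angle=mean_angle,
        mean_intensity=mean_intensity,
    )


def summarize_batch(
    result: TockyResult,
    manifest: SampleManifest,
    fsc_channel: str | None = "FSC",
    geometric: bool = False,
) -> pd.DataFrame:
    """One summary row per sample in the result (raw data re-read from the
    manifest for the MFI columns)."""
    rows = []
    for entry in manifest.entries:
        if entry.sample_id not in result.samples:
            continue
        raw = read_cell_matrix(entry, manifest.common_variables)
        s = summarize_sample(
            result.samples[entry.sample_id],
            raw,
            manifest.blue_channel,
            manifest.red_channel,
            fsc_channel=fsc_channel,
            group=entry.group,
            geometric=geometric,
        )
        row = {
            "sample_id": s.sample_id,
            "group": s.group,
            "n_total": s.n_total,
            "n_timer_positive": s.n_timer_positive,
        }
        row.update({f"frac_{k}": v for k, v in s.quadrant_fractions.items()})
        row.update(
            {
                "mfi_blue": s.mfi_blue,
                "mfi_red": s.mfi_red,
                "mean_fsc": s.mean_fsc,
                "mean_angle": s.mean_angle,
                "mean_intensity": s.mean_intensity,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def exclude_group(result: TockyResult, group: str) -> TockyResult:
    """Drop every sample of one group from downstream summaries — e.g. a
    0-hour timepoint whose red-only cells reflect in-vivo history rather
    than the stimulation under study."""
    defn = result.sample_definition
    available = sorted(set(defn["group"].astype(str)))
    if group not in available:
        raise ConfigurationError(f"unknown group {group!r}; available: {available}")
    keep_ids = set(defn.loc[defn["group"].astype(str) != group, "sample_id"])
    logger.info("excluding group %r (%d sample(s) removed)",
                group, len(result.samples) - len(keep_ids))
    return TockyResult(
        samples={k: v for k, v in result.samples.items() if k in keep_ids},
        thresholds=result.thresholds,
        params=result.params,
        counts=result.counts[result.counts["sample_id"].isin(keep_ids)].reset_index(drop=True),
        sample_definition=defn[defn["sample_id"].isin(keep_ids)].reset_index(drop=True),
        normalize=result.normalize,
    )


def _groups_in_order(result: TockyResult, group_order: list[str] | None) -> list[str]:
    seen = list(dict.fromkeys(result.sample_definition["group"].astype(str)))
    if group_order is None:
        return seen
    unknown = [g for g in group_order if g not in seen]
    if unknown:
        raise ConfigurationError(f"unknown group(s) in group_order: {unknown}")
    return list(group_order)


def _plot_frame(result: TockyResult, mode: str) -> pd.DataFrame:
    """Long-format plot data: group, sample_id, x, y — a pure projection of
    the transformed tables."""
    defn = result.sample_definition
    group_of = dict(zip(defn["sample_id"], defn["group"].astype(str)))
    frames = []
    for sid, t in result.samples.items():
        d = t.data
        if mode == "timer_fluorescence":
            x, y = d["blue_log"], d["red_log"]
        elif mode == "normalized_timer_fluorescence":
            pos = d["timer_positive"]
            x, y = d.loc[pos, "blue_norm"], d.loc[pos, "red_norm"]
        elif mode == "angle_intensity":
            pos = d["timer_positive"] & d["angle_deg"].notna()
            x, y = d.loc[pos, "angle_deg"], d.loc[pos, "intensity"]
        else:
            raise ConfigurationError(
                f"unknown plot mode {mode!r}; choose one of {PLOT_MODES}"
            )
        frames.append(pd.DataFrame({"group": group_of.get(sid, ""), "sample_id": sid,
                                    "x": x.to_numpy(), "y": y.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def plot_tocky(
    result: TockyResult,
    mode: str,
    output_dir: Path | str,
    group_order: list[str] | None = None,
) -> dict[str, Path]:
    """Render one panel per group for the requested mode and write both the
    figure (PNG) and the underlying plot-data CSV.

    Modes: ``timer_fluorescence`` (log blue vs log red with the threshold
    lines), ``normalized_timer_fluorescence`` (normalized blue vs red,
    Timer-positive cells), ``angle_intensity`` (angle 0-90 deg vs
    intensity).
    """
    if mode not in PLOT_MODES:
        raise ConfigurationError(f"unknown plot mode {mode!r}; choose one of {PLOT_MODES}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    data = _plot_frame(result, mode)
    groups = _groups_in_order(result, group_order)
    data = data[data["group"].isin(groups)]

    csv_path = output_dir / f"plot_{mode}.csv"
    data.to_csv(csv_path, index=False)

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ncol = min(len(groups), 4) or 1
    nrow = -(-max(len(groups), 1) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    thr = result.thresholds
    floor = result.params.log_floor
    for ax, group in zip(axes.flat, groups):
        sub = data[data["group"] == group]
        ax.scatter(sub["x"], sub["y"], s=2, alpha=0.4, linewidths=0)
        ax.set_title(str(group), fontsize=9)
        if mode == "timer_fluorescence":
            ax.axhline(float(log_transform([thr.red_threshold], floor)[0]), color="k", lw=0.7)
            ax.axvline(float(log_transform([thr.blue_threshold], floor)[0]), color="k", lw=0.7)
            ax.set_xlabel("log10 blue")
            ax.set_ylabel("log10 red")
        elif mode == "normalized_timer_fluorescence":
            ax.set_xlabel("normalized blue")
            ax.set_ylabel("normalized red")
        else:
            ax.set_xlim(0, 90)
            ax.set_xlabel("Timer Angle (deg)")
            ax.set_ylabel("Timer Intensity")
    for ax in axes.flat[len(groups):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig_path = output_dir / f"plot_{mode}.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return {"figure": fig_path, "data": csv_path}
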