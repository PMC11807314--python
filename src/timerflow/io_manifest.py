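"""Sample discovery, manifest construction, and per-cell CSV ingestion.

A run starts from a directory of per-sample CSV exports (rows = cells,
columns = channels) plus one designated Timer-negative control file of the
same shape. This module discovers the files, identifies the channels common
to all of them, and records the result as a :class:`SampleManifest` that is
serialized to plain text so a run is fully reproducible from its output
directory.

The CSV dialect is the one flow-cytometry software exports: comma-delimited,
mandatory header row, ``.`` decimal. Channel identification is by exact
header name supplied by the user; detector names vary too much between
instruments for auto-detection to be safe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError

logger = logging.getLogger("timerflow")

SAMPLE_DEFINITION_FILE = "sample_definition.csv"
COMMON_VARIABLES_FILE = "common_variables.txt"
MANIFEST_META_FILE = "manifest.yaml"

ROLE_SAMPLE = "sample"
ROLE_NEGATIVE_CONTROL = "negative_control"


@dataclass(frozen=True)
class SampleEntry:
    """One file in a run: an experimental sample or the negative control."""

    sample_id: str
    path: Path
    role: str = ROLE_SAMPLE
    group: str = ""

    def __post_init__(self) -> None:
        if self.role not in (ROLE_SAMPLE, ROLE_NEGATIVE_CONTROL):
            raise ConfigurationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class SampleManifest:
    """The file set of a run plus the channels shared by every file."""

    entries: tuple[SampleEntry, ...]
    common_variables: tuple[str, ...]
    blue_channel: str
    red_channel: str
    output_dir: Path | None = None

    @property
    def negative_control(self) -> SampleEntry:
        return next(e for e in self.entries if e.role == ROLE_NEGATIVE_CONTROL)

    @property
    def samples(self) -> tuple[SampleEntry, ...]:
        return tuple(e for e in self.entries if e.role == ROLE_SAMPLE)


@dataclass
class CellMatrix:
    """Per-cell channel table for one sample (raw fluorescence, a.u.)."""

    sample_id: str
    data: pd.DataFrame = field(repr=False)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def channel(self, name: str):
        """Raw values of one channel as a numpy array."""
        return self.data[name].to_numpy(dtype=float)


def discover_files(directory: Path | str, include_pattern: str = "*.csv") -> list[Path]:
    """List files in ``directory`` matching a glob, lexicographically sorted.

    Deterministic by construction; an empty list is a valid result.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigurationError(f"not a directory: {directory}")
    return sorted(p for p in directory.glob(include_pattern) if p.is_file())


def _read_header(path: Path) -> list[str]:
    try:
        return list(pd.read_csv(path, nrows=0).columns)
    except Exception as exc:  # pragma: no cover - message path
        raise DataError(f"cannot read header of {path}: {exc}") from exc


def build_manifest(
    paths: list[Path | str],
    negative_control: Path | str,
    blue_channel: str,
    red_channel: str,
    groups: dict[str, str] | None = None,
    output_dir: Path | str | None = None,
) -> SampleManifest:
    """Build (and optionally serialize) a manifest from explicit file paths.

    ``common_variables`` is the intersection of the header sets of *all*
    files, negative control included, stored sorted so the result does not
    depend on the order in which files were listed. Sample ids are file
    stems and must be unique. If the blue or red channel is missing from the
    intersection the error message reports, per file, whether the channel is
    present — the fastest way to spot the one export with renamed detectors.
    """
    paths = [Path(p) for p in paths]
    negative_control = Path(negative_control)
    if not paths:
        raise ConfigurationError("no input files given")
    if negative_control not in paths:
        raise ConfigurationError(
            f"negative control {negative_control} is not among the input files"
        )
    if blue_channel == red_channel:
        raise ConfigurationError("blue and red channels must be distinct")

    headers = {p: _read_header(p) for p in paths}
    common: set[str] = set.intersection(*(set(h) for h in headers.values()))
    for ch, label in ((blue_channel, "blue"), (red_channel, "red")):
        if ch not in common:
            report = "\n".join(
                f"  {p.name}: {'present' if ch in headers[p] else 'ABSENT'}"
                for p in paths
            )
            raise DataError(
                f"{label} channel {ch!r} is not common to all files:\n{report}"
            )

    groups = groups or {}
    entries = []
    for p in paths:
        sid = p.stem
        role = ROLE_NEGATIVE_CONTROL if p == negative_control else ROLE_SAMPLE
        entries.append(SampleEntry(sid, p, role, groups.get(sid, "")))
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate sample ids: {dupes}")

    manifest = SampleManifest(
        entries=tuple(entries),
        common_variables=tuple(sorted(common)),
        blue_channel=blue_channel,
        red_channel=red_channel,
        output_dir=Path(output_dir) if output_dir is not None else None,
    )
    if manifest.output_dir is not None:
        write_manifest(manifest, manifest.output_dir)
    return manifest


def write_manifest(manifest: SampleManifest, directory: Path | str) -> None:
    """Serialize a manifest as plain text: sample definition CSV, the
    common-variable list (one name per line), and a small YAML with the
    channel designations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"sample_id": e.sample_id, "path": str(e.path), "role": e.role, "group": e.group}
            for e in manifest.entries
        ]
    ).to_csv(directory / SAMPLE_DEFINITION_FILE, index=False)
    (directory / COMMON_VARIABLES_FILE).write_text(
        "\n".join(manifest.common_variables) + "\n"
    )
    meta = {
        "blue_channel": manifest.blue_channel,
        "red_channel": manifest.red_channel,
        "output_dir": str(manifest.output_dir) if manifest.output_dir else None,
    }
    (directory / MANIFEST_META_FILE).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_manifest(directory: Path | str) -> SampleManifest:
    """Parse a manifest previously written by :func:`write_manifest`."""
    directory = Path(directory)
    defn = directory / SAMPLE_DEFINITION_FILE
    if not defn.is_file():
        raise ConfigurationError(f"no {SAMPLE_DEFINITION_FILE} in {directory}")
    table = pd.read_csv(defn, dtype=str).fillna("")
    entries = tuple(
        SampleEntry(r.sample_id, Path(r.path), r.role, r.group)
        for r in table.itertuples()
    )
    variables = tuple(
        (directory / COMMON_VARIABLES_FILE).read_text().split()
    )
    meta = yaml.safe_load((directory / MANIFEST_META_FILE).read_text())
    return SampleManifest(
        entries=entries,
        common_variables=variables,
        blue_channel=meta["blue_channel"],
        red_channel=meta["red_channel"],
        output_dir=Path(meta["output_dir"]) if meta.get("output_dir") else None,
    )


def read_cell_matrix(entry: SampleEntry, variables: list[str] | tuple[str, ...]) -> CellMatrix:
    """Read one sample's CSV restricted to ``variables``.

    Original row order is preserved. Cells (rows) with a missing or
    non-numeric value in any requested variable are dropped and the count is
    logged — flow exports occasionally contain stray ``NA`` tokens.
    """
    try:
        raw = pd.read_csv(entry.path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty or unparseable file: {entry.path}") from exc
    except Exception as exc:
        raise DataError(f"cannot parse {entry.path}: {exc}") from exc
    missing = [v for v in variables if v not in raw.columns]
    if missing:
        raise DataError(f"{entry.path}: missing column(s) {missing}")
    sub = raw[list(variables)].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d row(s) with missing/non-numeric values",
                    entry.sample_id, dropped)
    sub = sub.loc[keep].reset_index(drop=True)
    if sub.empty:
        raise DataError(f"no usable cells in {entry.path}")
    return CellMatrix(entry.sample_id, sub)


def entry_for_path(path: Path | str, role: str = ROLE_SAMPLE, group: str = "") -> SampleEntry:
    """Convenience: a standalone entry for a file outside a manifest."""
    path = Path(path)
    return SampleEntry(path.stem, path, role, group)


def with_output_dir(manifest: SampleManifest, directory: Path | str) -> SampleManifest:
    return replace(manifest, output_dir=Path(directory))
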