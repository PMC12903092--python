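"""Canonical spike-table I/O and plate geometry.

Spike timestamps are exchanged as a plain CSV with columns
``well_id, electrode_id, time_s`` plus a YAML manifest holding the recording
duration, sampling rate and per-well metadata. Times are seconds from recording
start; every interval in this package is half-open ``[start, end)``.

The plate is a 48-well layout with 16 extracellular electrodes per well in a
4x4 grid (50 um diameter, 350 um pitch); electrodes are named ``R{row}C{col}``
and wells ``A1``..``F8``.
"""

from __future__ import annotations

import csv
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PlateLayout",
    "SpikeRecording",
    "read_spike_table",
    "write_spike_table",
    "validate_recording",
]


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multiwell MEA plate.

    Defaults describe a 48-well plate with 16 electrodes per well embedded in
    a 4x4 grid (electrode diameter 50 um, spacing 350 um).
    """

    n_wells: int = 48
    rows: int = 4
    cols: int = 4
    electrode_spacing_um: float = 350.0
    electrode_diameter_um: float = 50.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_wells < 1:
            raise ValueError("plate dimensions must be positive")

    @property
    def electrodes_per_well(self) -> int:
        return self.rows * self.cols

    @property
    def electrode_ids(self) -> tuple[str, ...]:
        """Electrode identifiers within a well, row-major: R1C1..R{rows}C{cols}."""
        return tuple(
            f"R{r}C{c}" for r in range(1, self.rows + 1) for c in range(1, self.cols + 1)
        )

    @property
    def well_ids(self) -> tuple[str, ...]:
        """Well identifiers A1..F8 (row letters, 8 columns per row)."""
        n_cols = 8
        letters = string.ascii_uppercase
        ids = []
        for i in range(self.n_wells):
            ids.append(f"{letters[i // n_cols]}{i % n_cols + 1}")
        return tuple(ids)


@dataclass
class SpikeRecording:
    """Spike timestamps for one well: a sorted array of seconds per electrode.

    ``spike_times`` maps electrode id -> float array; silent electrodes are
    present with empty arrays so electrode counts stay well-defined.
    """

    well_id: str
    spike_times: dict[str, np.ndarray]
    duration: float = 300.0
    sampling_rate: float = 12500.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = {
            e: np.asarray(t, dtype=float) for e, t in self.spike_times.items()
        }

    @property
    def n_electrodes(self) -> int:
        return len(self.spike_times)

    @property
    def electrode_ids(self) -> list[str]:
        return list(self.spike_times)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times.values()))

    def active_electrodes(self) -> list[str]:
        """Electrodes with at least one spike."""
        return [e for e, t in self.spike_times.items() if t.size > 0]


def validate_recording(rec: SpikeRecording) -> list[str]:
    """Check SpikeRecording invariants, returning human-readable violations.

    Checks per electrode: non-decreasing times, bounds ``0 <= t <= duration``,
    and alignment to the sampling grid (multiples of ``1/sampling_rate`` within
    1e-9 s). An empty list means the recording is valid.
    """
    violations: list[str] = []
    dt = 1.0 / rec.sampling_rate
    for elec, times in rec.spike_times.items():
        if times.size == 0:
            continue
        if np.any(np.diff(times) < 0):
            violations.append(f"electrode {elec}: spike times not sorted")
        if times[0] < 0:
            violations.append(f"electrode {elec}: negative spike time {times[0]}")
        if times[-1] > rec.duration:
            violations.append(
                f"electrode {elec}: spike time {times[-1]} exceeds duration {rec.duration}"
            )
        offgrid = np.abs(times / dt - np.round(times / dt)) * dt
        if np.any(offgrid > 1e-9):
            i = int(np.argmax(offgrid))
            violations.append(
                f"electrode {elec}: time {times[i]} not on the {rec.sampling_rate} Hz sampling grid"
            )
    return violations


def _read_manifest(path: Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh) or {}
    return manifest


def read_spike_table(
    path: str | Path,
    layout: PlateLayout | None = None,
    manifest_path: str | Path | None = None,
) -> list[SpikeRecording]:
    """Read the canonical spike CSV (+ YAML manifest) into SpikeRecordings.

    Parameters
    ----------
    path
        CSV with header ``well_id, electrode_id, time_s``.
    layout
        Plate geometry; defaults to the standard 48-well/16-electrode plate.
        Electrode ids not in the layout are a hard error naming the row.
    manifest_path
        YAML manifest (``duration_s``, ``sampling_rate_hz``, ``wells`` metadata
        map, optional ``electrodes`` per well). Defaults to ``<path's
        directory>/manifest.yaml`` if that file exists.

    Returns one recording per well appearing in the CSV or manifest; electrodes
    with no spikes are present with empty arrays. Rows may come in any order.
    """
    path = Path(path)
    layout = layout or PlateLayout()
    if manifest_path is None:
        candidate = path.parent / "manifest.yaml"
        manifest = _read_manifest(candidate) if candidate.exists() else {}
    else:
        manifest = _read_manifest(Path(manifest_path))

    duration = float(manifest.get("duration_s", 300.0))
    sampling_rate = float(manifest.get("sampling_rate_hz", 12500.0))
    well_meta: Mapping[str, dict] = manifest.get("wells", {}) or {}
    valid_electrodes = set(layout.electrode_ids)
    for elist in (manifest.get("electrodes", {}) or {}).values():
        valid_electrodes.update(elist)

    per_well: dict[str, dict[str, list[float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"well_id", "electrode_id", "time_s"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns well_id, electrode_id, time_s; got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            well = row["well_id"]
            elec = row["electrode_id"]
            try:
                t = float(row["time_s"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} row {i}: malformed time_s {row['time_s']!r}") from exc
            if elec not in valid_electrodes:
                raise ValueError(f"{path} row {i}: unknown electrode id {elec!r}")
            if t < 0 or t > duration:
                raise ValueError(
                    f"{path} row {i}: time_s={t} outside [0, {duration}]"
                )
            per_well.setdefault(well, {}).setdefault(elec, []).append(t)

    # Wells listed in the manifest are present even if entirely silent.
    all_wells = sorted(set(per_well) | set(well_meta))
    if not all_wells:
        logger.warning("spike table %s contains no wells", path)

    recordings = []
    electrode_lists: Mapping[str, list[str]] = manifest.get("electrodes", {}) or {}
    for well in all_wells:
        electrodes = electrode_lists.get(well, list(layout.electrode_ids))
        spikes = {
            e: np.sort(np.asarray(per_well.get(well, {}).get(e, []), dtype=float))
            for e in electrodes
        }
        recordings.append(
            SpikeRecording(
                well_id=well,
                spike_times=spikes,
                duration=duration,
                sampling_rate=sampling_rate,
                metadata=dict(well_meta.get(well, {})),
            )
        )
    return recordings


def write_spike_table(
    recordings: Sequence[SpikeRecording],
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> Path:
    """Write recordings to the canonical CSV + manifest.

    The manifest preserves duration, sampling rate and per-well metadata, so
    ``read_spike_table(write_spike_table(x))`` round-trips exactly (silent
    electrodes included). Returns the CSV path.
    """
    path = Path(path)
    if manifest_path is None:
        manifest_path = path.parent / "manifest.yaml"
    manifest_path = Path(manifest_path)

    if not recordings:
        raise ValueError("no recordings to write")
    durations = {r.duration for r in recordings}
    rates = {r.sampling_rate for r in recordings}
    if len(durations) > 1 or len(rates) > 1:
        raise ValueError("recordings in one table must share duration and sampling rate")

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well_id", "electrode_id", "time_s"])
        for rec in sorted(recordings, key=lambda r: r.well_id):
            for elec in rec.electrode_ids:
                for t in rec.spike_times[elec]:
                    writer.writerow([rec.well_id, elec, repr(float(t))])

    manifest = {
        "duration_s": float(durations.pop()),
        "sampling_rate_hz": float(rates.pop()),
        "wells": {r.well_id: dict(r.metadata) for r in recordings},
        "electrodes": {r.well_id: list(r.electrode_ids) for r in recordings},
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
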