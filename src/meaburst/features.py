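"""Per-well network-activity parameters (the 39-parameter fingerprint).

The catalogue groups parameters in four tiers, all computable from the spike
trains plus the electrode-burst and classified network-burst detections of a
single well:

* spike level (8): firing-rate mean/SD/CoV across active electrodes, total
  spike count, active-electrode count, inter-spike-interval mean/SD/CoV;
* electrode-burst level (14): burst rate, burst duration mean/SD/CoV,
  within-burst ISI mean/SD, burst percentage mean/SD, electrode IBI
  mean/SD/CoV, spikes-per-burst mean/SD, bursting-electrode count;
* network-burst level (12): network burst frequency (main bursts per 5-min
  recording), duration mean/SD/CoV, network IBI mean/SD/CoV (end-to-start
  gaps between consecutive main bursts), network burst percentage,
  participation mean/SD, within-burst population firing rate mean/SD;
* fragmentation level (5): fragmentation percentage, fragment duration
  mean/SD, fragment gap mean, fragments-per-main mean.

Well-level aggregates weight electrodes equally (not spike-weighted); every
CoV column equals the SD column divided by the mean column of its base
quantity. Statistics requiring more events than are present are missing
(NaN), never zero. Fragmented network bursts are excluded from every
main-burst parameter and analysed separately in the fragmentation tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from meaburst.electrode_bursts import ElectrodeBurst, electrode_burst_stats
from meaburst.network_bursts import NetworkBurst, fragmentation_percentage
from meaburst.spike_io import SpikeRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureCatalogue",
    "DEFAULT_CATALOGUE",
    "extract_features",
    "aggregate_table",
    "normalize_to_control",
]

_SPIKE_LEVEL = [
    "firing_rate_mean",
    "firing_rate_sd",
    "firing_rate_cov",
    "total_spikes",
    "active_electrodes",
    "isi_mean",
    "isi_sd",
    "isi_cov",
]
_EBURST_LEVEL = [
    "eburst_rate",
    "eburst_duration_mean",
    "eburst_duration_sd",
    "eburst_duration_cov",
    "eburst_isi_within_mean",
    "eburst_isi_within_sd",
    "burst_percentage_mean",
    "burst_percentage_sd",
    "eburst_ibi_mean",
    "eburst_ibi_sd",
    "eburst_ibi_cov",
    "spikes_per_eburst_mean",
    "spikes_per_eburst_sd",
    "bursting_electrodes",
]
_NBURST_LEVEL = [
    "nb_frequency",
    "nb_duration_mean",
    "nb_duration_sd",
    "nb_duration_cov",
    "nb_ibi_mean",
    "nb_ibi_sd",
    "nb_ibi_cov",
    "network_burst_percentage",
    "nb_participation_mean",
    "nb_participation_sd",
    "nb_firing_rate_mean",
    "nb_firing_rate_sd",
]
_FRAG_LEVEL = [
    "fragmentation_percentage",
    "fragment_duration_mean",
    "fragment_duration_sd",
    "fragment_gap_mean",
    "fragments_per_main_mean",
]


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered, named set of per-well parameters.

    The default catalogue has exactly 39 unique names. A custom list (e.g. a
    published parameter set) can be loaded from YAML without code changes; the
    names must be a subset of the computable parameters.
    """

    names: tuple[str, ...] = field(
        default_factory=lambda: tuple(_SPIKE_LEVEL + _EBURST_LEVEL + _NBURST_LEVEL + _FRAG_LEVEL)
    )

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalogue names must be unique")
        unknown = set(self.names) - set(_SPIKE_LEVEL + _EBURST_LEVEL + _NBURST_LEVEL + _FRAG_LEVEL)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalogue":
        with open(path) as fh:
            names = yaml.safe_load(fh)
        return cls(names=tuple(names))


DEFAULT_CATALOGUE = FeatureCatalogue()


def _nanstat(values: Sequence[float], fn) -> float:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    return float(fn(v)) if v.size else float("nan")


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    m = float(values.mean())
    s = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return m, s


def extract_features(
    rec: SpikeRecording,
    ebursts: Mapping[str, Sequence[ElectrodeBurst]],
    nbursts: Sequence[NetworkBurst],
    catalogue: FeatureCatalogue = DEFAULT_CATALOGUE,
) -> dict[str, float]:
    """Compute the catalogue parameters for one well.

    ``ebursts`` maps electrode id -> bursts detected on that electrode's
    train; ``nbursts`` are the well's classified network bursts. Raises if an
    electrode id in ``ebursts`` is absent from the recording.
    """
    unknown = set(ebursts) - set(rec.electrode_ids)
    if unknown:
        raise ValueError(f"electrode ids not in recording: {sorted(unknown)}")

    f: dict[str, float] = {}
    duration = rec.duration

    # ---- spike level -----------------------------------------------------
    active = rec.active_electrodes()
    rates = np.array([rec.spike_times[e].size / duration for e in active], dtype=float)
    f["firing_rate_mean"], f["firing_rate_sd"] = _mean_sd(rates)
    f["firing_rate_cov"] = f["firing_rate_sd"] / f["firing_rate_mean"] if rates.size else float("nan")
    f["total_spikes"] = float(rec.total_spikes)
    f["active_electrodes"] = float(len(active))
    isi_means = [float(np.diff(rec.spike_times[e]).mean())
                 for e in active if rec.spike_times[e].size >= 2]
    isi_sds = [float(np.diff(rec.spike_times[e]).std(ddof=1))
               for e in active if rec.spike_times[e].size >= 3]
    f["isi_mean"] = _nanstat(isi_means, np.mean)
    f["isi_sd"] = _nanstat(isi_sds, np.mean)
    f["isi_cov"] = f["isi_sd"] / f["isi_mean"]

    # ---- electrode-burst level (equal electrode weighting) ---------------
    stats = {
        e: electrode_burst_stats(ebursts.get(e, []), rec.spike_times[e], duration)
        for e in rec.electrode_ids
    }
    bursting = [e for e in rec.electrode_ids if ebursts.get(e)]

    def emean(key: str, subset: Sequence[str]) -> float:
        return _nanstat([stats[e][key] for e in subset], np.mean)

    def esd(key: str, subset: Sequence[str]) -> float:
        vals = [stats[e][key] for e in subset if np.isfinite(stats[e][key])]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    f["eburst_rate"] = emean("burst_rate_per_min", rec.electrode_ids)
    f["eburst_duration_mean"] = emean("burst_duration_mean", bursting)
    f["eburst_duration_sd"] = emean("burst_duration_sd", bursting)
    f["eburst_duration_cov"] = f["eburst_duration_sd"] / f["eburst_duration_mean"]
    f["eburst_isi_within_mean"] = emean("isi_within_burst_mean", bursting)
    f["eburst_isi_within_sd"] = emean("isi_within_burst_sd", bursting)
    f["burst_percentage_mean"] = emean("burst_percentage", active)
    f["burst_percentage_sd"] = esd("burst_percentage", active)
    f["eburst_ibi_mean"] = emean("ibi_mean", bursting)
    f["eburst_ibi_sd"] = emean("ibi_sd", bursting)
    f["eburst_ibi_cov"] = f["eburst_ibi_sd"] / f["eburst_ibi_mean"]
    f["spikes_per_eburst_mean"] = emean("spikes_per_burst_mean", bursting)
    f["spikes_per_eburst_sd"] = emean("spikes_per_burst_sd", bursting)
    f["bursting_electrodes"] = float(len(bursting))

    # ---- network-burst level (main bursts only) --------------------------
    mains = [b for b in nbursts if b.klass == "main"]
    frags = [b for b in nbursts if b.klass == "fragment"]
    f["nb_frequency"] = len(mains) * (300.0 / duration)
    durs = np.array([b.duration for b in mains])
    f["nb_duration_mean"], f["nb_duration_sd"] = _mean_sd(durs)
    f["nb_duration_cov"] = f["nb_duration_sd"] / f["nb_duration_mean"]
    if len(mains) >= 2:
        ibis = np.array([mains[i + 1].start - mains[i].end for i in range(len(mains) - 1)])
        f["nb_ibi_mean"], f["nb_ibi_sd"] = _mean_sd(ibis)
        f["nb_ibi_cov"] = f["nb_ibi_sd"] / f["nb_ibi_mean"]
    else:
        f["nb_ibi_mean"] = f["nb_ibi_sd"] = f["nb_ibi_cov"] = float("nan")

    total_spikes = rec.total_spikes
    n_elec = max(rec.n_electrodes, 1)
    if total_spikes and mains:
        in_main = 0
        for e in rec.electrode_ids:
            t = rec.spike_times[e]
            for b in mains:
                in_main += int(np.count_nonzero((t >= b.start) & (t < b.end)))
        f["network_burst_percentage"] = 100.0 * in_main / total_spikes
    else:
        f["network_burst_percentage"] = 0.0 if total_spikes else float("nan")
    part = np.array([100.0 * len(b.participating_electrodes) / n_elec for b in mains])
    f["nb_participation_mean"], f["nb_participation_sd"] = _mean_sd(part)
    nb_rates = []
    for b in mains:
        n_part = len(b.participating_electrodes)
        if n_part == 0 or b.duration <= 0:
            continue
        n_in = sum(
            int(np.count_nonzero((rec.spike_times[e] >= b.start) & (rec.spike_times[e] < b.end)))
            for e in b.participating_electrodes
        )
        nb_rates.append(n_in / (b.duration * n_part))
    f["nb_firing_rate_mean"], f["nb_firing_rate_sd"] = _mean_sd(np.asarray(nb_rates))

    # ---- fragmentation level (fragments only) ----------------------------
    f["fragmentation_percentage"] = fragmentation_percentage(nbursts)
    fdurs = np.array([b.duration for b in frags])
    f["fragment_duration_mean"], f["fragment_duration_sd"] = _mean_sd(fdurs)
    ordered = sorted(nbursts, key=lambda b: b.start)
    gaps = [
        ordered[i].start - ordered[i - 1].end
        for i in range(1, len(ordered))
        if ordered[i].klass == "fragment"
    ]
    f["fragment_gap_mean"] = _nanstat(gaps, np.mean)
    f["fragments_per_main_mean"] = len(frags) / len(mains) if mains else float("nan")

    return {name: f[name] for name in catalogue.names}


def aggregate_table(
    wells: Sequence[tuple[SpikeRecording, Mapping[str, Sequence[ElectrodeBurst]], Sequence[NetworkBurst]]],
    catalogue: FeatureCatalogue = DEFAULT_CATALOGUE,
    metadata_keys: Sequence[str] = ("line", "group", "DIV", "treatment", "batch"),
) -> pd.DataFrame:
    """Build the tidy wells x parameters feature table.

    One row per (well, DIV); metadata columns precede the catalogue columns in
    stable catalogue order. Raises on duplicate (well, DIV) rows.
    """
    rows = []
    for rec, eb, nb in wells:
        row: dict[str, object] = {"well_id": rec.well_id}
        for k in metadata_keys:
            row[k] = rec.metadata.get(k)
        row.update(extract_features(rec, eb, nb, catalogue))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["well_id", *metadata_keys, *catalogue.names])
    if df.duplicated(subset=["well_id", "DIV"]).any():
        raise ValueError("duplicate (well, DIV) rows in feature table")
    return df


def normalize_to_control(
    table: pd.DataFrame,
    value_column: str,
    control_mask: pd.Series | np.ndarray,
) -> pd.Series:
    """Divide a parameter column by the mean of its control rows.

    The control mean itself maps to 1. Raises if the control mean is zero,
    missing, or no control rows exist.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("no control rows selected")
    control_mean = table.loc[control_mask, value_column].mean()
    if not np.isfinite(control_mean) or control_mean == 0:
        raise ValueError(f"control mean of {value_column!r} is zero or missing")
    return table[value_column] / control_mean
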