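"""Per-electrode burst detection with the maximum-ISI algorithm.

A burst is a run of consecutive spikes whose inter-spike intervals are all at
most ``max_isi`` (default 0.1 s). Candidate runs separated by a gap shorter
than ``merge_gap`` (default 0.05 s) are merged, and only candidates with at
least ``min_spikes`` spikes (default 5) and a duration strictly greater than
``min_duration`` (default 0.05 s) are kept. The processing order is fixed as
group -> merge -> filter, so physiologically contiguous firing that is split
by a brief pause can still pass the spike-count filter.

Boundary conventions: an ISI exactly equal to ``max_isi`` joins the burst
(<=); a gap exactly equal to ``merge_gap`` does not merge (<). Burst start and
end are the first and last spike times, not padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ElectrodeBurstParams",
    "ElectrodeBurst",
    "detect_electrode_bursts",
    "electrode_burst_stats",
]


@dataclass(frozen=True)
class ElectrodeBurstParams:
    max_isi: float = 0.1
    min_spikes: int = 5
    min_duration: float = 0.05
    merge_gap: float = 0.05
    #: apply the spike-count/duration filter before merging instead of after
    filter_before_merge: bool = False

    def __post_init__(self) -> None:
        if min(self.max_isi, self.min_duration, self.merge_gap) <= 0 or self.min_spikes <= 0:
            raise ValueError("all electrode-burst parameters must be positive")


@dataclass(frozen=True)
class ElectrodeBurst:
    electrode: str
    start: float
    end: float
    spike_count: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def _group_candidates(times: np.ndarray, max_isi: float) -> list[tuple[int, int]]:
    """Split spikes into maximal runs with all ISIs <= max_isi.

    Returns (start_index, stop_index) pairs, stop exclusive.
    """
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_isi) + 1
    edges = np.concatenate(([0], breaks, [times.size]))
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def detect_electrode_bursts(
    times: Sequence[float] | np.ndarray,
    params: ElectrodeBurstParams = ElectrodeBurstParams(),
    electrode: str = "",
) -> list[ElectrodeBurst]:
    """Detect bursts on one electrode's sorted spike train.

    Raises ``ValueError`` on unsorted input. Returned bursts are sorted and
    disjoint.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")

    def _passes(a: int, b: int) -> bool:
        return (b - a) >= params.min_spikes and (times[b - 1] - times[a]) > params.min_duration

    candidates = _group_candidates(times, params.max_isi)
    if params.filter_before_merge:
        candidates = [c for c in candidates if _passes(*c)]

    merged: list[tuple[int, int]] = []
    for a, b in candidates:
        if merged and (times[a] - times[merged[-1][1] - 1]) < params.merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    kept = merged if params.filter_before_merge else [c for c in merged if _passes(*c)]
    return [
        ElectrodeBurst(electrode=electrode, start=float(times[a]), end=float(times[b - 1]),
                       spike_count=b - a)
        for a, b in kept
    ]


def electrode_burst_stats(
    bursts: Sequence[ElectrodeBurst],
    times: Sequence[float] | np.ndarray,
    duration: float,
) -> dict[str, float]:
    """Summary statistics for one electrode's bursts.

    Keys: ``burst_rate_per_min``, ``burst_duration_mean/sd``,
    ``isi_within_burst_mean/sd``, ``burst_percentage`` (percent of spikes
    falling inside any burst), ``ibi_mean/sd/cov`` (end-to-start gaps between
    consecutive bursts). Statistics that need more data than is present (e.g.
    IBI with fewer than two bursts) are NaN, never zero.
    """
    times = np.asarray(times, dtype=float)
    n_spikes = times.size
    nan = float("nan")
    out = {
        "burst_rate_per_min": len(bursts) / duration * 60.0,
        "burst_duration_mean": nan,
        "burst_duration_sd": nan,
        "isi_within_burst_mean": nan,
        "isi_within_burst_sd": nan,
        "burst_percentage": nan,
        "ibi_mean": nan,
        "ibi_sd": nan,
        "ibi_cov": nan,
        "spikes_per_burst_mean": nan,
        "spikes_per_burst_sd": nan,
    }
    if n_spikes:
        in_burst = 0
        for b in bursts:
            in_burst += int(np.sum((times >= b.start) & (times <= b.end)))
        out["burst_percentage"] = 100.0 * in_burst / n_spikes
    if bursts:
        durs = np.array([b.duration for b in bursts])
        counts = np.array([b.spike_count for b in bursts], dtype=float)
        out["burst_duration_mean"] = float(durs.mean())
        out["burst_duration_sd"] = float(durs.std(ddof=1)) if len(bursts) > 1 else nan
        out["spikes_per_burst_mean"] = float(counts.mean())
        out["spikes_per_burst_sd"] = float(counts.std(ddof=1)) if len(bursts) > 1 else nan
        # ISIs pooled over this electrode's bursts
        isis = []
        for b in bursts:
            inside = times[(times >= b.start) & (times <= b.end)]
            isis.extend(np.diff(inside))
        if isis:
            isis = np.asarray(isis)
            out["isi_within_burst_mean"] = float(isis.mean())
            out["isi_within_burst_sd"] = float(isis.std(ddof=1)) if isis.size > 1 else nan
    if len(bursts) >= 2:
        ibis = np.array([bursts[i + 1].start - bursts[i].end for i in range(len(bursts) - 1)])
        out["ibi_mean"] = float(ibis.mean())
        out["ibi_sd"] = float(ibis.std(ddof=1)) if ibis.size > 1 else nan
        if ibis.size > 1 and ibis.mean() > 0:
            out["ibi_cov"] = float(ibis.std(ddof=1) / ibis.mean())
    return out
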