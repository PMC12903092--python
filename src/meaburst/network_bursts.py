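"""Well-level network burst detection and fragmented-burst classification.

Pipeline: spike timestamps are binned at 2 ms, each electrode's binned train
is smoothed with a Gaussian kernel of 70 ms total support (sigma = window/6,
unit-sum, reflect padding), the smoothed signals are z-scored per electrode,
averaged across electrodes, and the combined signal is smoothed again with
the same kernel. Supra-threshold runs of the combined signal — threshold from
Otsu's between-class-variance criterion on a 256-bin histogram — become
candidate network-burst intervals, kept if at least 25% of electrodes fire
inside the interval, the duration exceeds 0.1 s, and at least 25% of the
actively participating electrodes sustain a within-interval firing rate of at
least 12 Hz.

Fragmented network bursts are particularly short bursts (< 0.32 s) trailing a
main burst (>= 0.32 s) by no more than 1.1 s; fragments may chain, the gap
being measured to the immediately preceding burst of the chain by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from meaburst.spike_io import SpikeRecording

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkBurstParams",
    "NetworkBurst",
    "bin_spikes",
    "gaussian_kernel",
    "gaussian_smooth",
    "combine_standardized",
    "otsu_threshold",
    "detect_network_bursts",
    "classify_fragmented",
    "fragmentation_percentage",
]


@dataclass(frozen=True)
class NetworkBurstParams:
    bin_width: float = 0.002
    gauss_window: float = 0.070
    min_participation: float = 0.25
    min_duration: float = 0.1
    min_rate: float = 12.0
    rate_fraction: float = 0.25
    main_min_duration: float = 0.32
    frag_max_gap: float = 1.1
    otsu_bins: int = 256
    #: measure the fragment gap to the anchoring main burst instead of to the
    #: immediately preceding burst of the chain
    gap_to_main: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.gauss_window < self.bin_width:
            raise ValueError("gauss_window must be at least one bin wide")
        for f in (self.min_participation, self.rate_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")
        if self.frag_max_gap <= 0:
            raise ValueError("frag_max_gap must be positive")


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    participating_electrodes: frozenset[str] = frozenset()
    klass: str = "unclassified"  # main | fragment | unclassified
    anchor: int | None = None  # index of the anchoring main burst, fragments only

    @property
    def duration(self) -> float:
        return self.end - self.start


def bin_spikes(rec: SpikeRecording, bin_width: float = 0.002) -> tuple[np.ndarray, list[str]]:
    """Bin each electrode's spikes into counts of width ``bin_width``.

    Bin ``b`` covers ``[b*dt, (b+1)*dt)``; a spike at exactly a bin edge falls
    in the later bin. Returns (electrodes x bins count matrix, electrode ids).
    """
    n_bins = int(math.ceil(rec.duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    electrodes = rec.electrode_ids
    counts = np.zeros((len(electrodes), n_bins), dtype=float)
    for i, e in enumerate(electrodes):
        t = rec.spike_times[e]
        if t.size:
            # half-open bins: spike at edge k*dt goes into bin k
            idx = np.minimum((t / bin_width).astype(int), n_bins - 1)
            np.add.at(counts[i], idx, 1.0)
    assert counts.sum() == rec.total_spikes
    del edges
    return counts, electrodes


def gaussian_kernel(window: float, bin_width: float) -> np.ndarray:
    """Unit-sum truncated Gaussian with total support ``window``.

    The window is read as +-3 sigma, i.e. sigma = window/6; at the default
    70 ms window and 2 ms bins the kernel spans 35 bins.
    """
    half = max(int(round(window / bin_width)) // 2, 1)
    sigma = window / 6.0 / bin_width
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(signal: np.ndarray, window: float, bin_width: float) -> np.ndarray:
    """Convolve with the unit-sum Gaussian kernel, reflect-padded ends.

    Output length equals input length; a constant signal is unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if window < bin_width:
        raise ValueError("window must be at least one bin wide")
    k = gaussian_kernel(window, bin_width)
    half = (k.size - 1) // 2
    if signal.size == 0:
        return signal.copy()
    pad = min(half, signal.size - 1)
    if pad > 0:
        padded = np.concatenate([signal[pad:0:-1], signal, signal[-2:-2 - pad:-1]])
    else:
        padded = signal
    if pad < half:  # very short signals: extend with edge values
        padded = np.concatenate(
            [np.full(half - pad, padded[0]), padded, np.full(half - pad, padded[-1])]
        )
    return np.convolve(padded, k, mode="valid")


def combine_standardized(
    smoothed: np.ndarray,
    window: float,
    bin_width: float,
    electrode_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Z-score each electrode's smoothed signal, average, and re-smooth.

    Zero-variance (silent or constant) electrodes are dropped with a log note;
    if none remain, raises ``ValueError("no active electrodes")``.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    sd = smoothed.std(axis=1)
    active = sd > 0
    if not np.any(active):
        raise ValueError("no active electrodes")
    n_dropped = int((~active).sum())
    if n_dropped:
        if electrode_ids is not None:
            dropped = [e for e, a in zip(electrode_ids, active) if not a]
            logger.info("dropping %d zero-variance electrodes: %s", n_dropped, dropped)
        else:
            logger.info("dropping %d zero-variance electrodes", n_dropped)
    z = (smoothed[active] - smoothed[active].mean(axis=1, keepdims=True)) / sd[active, None]
    combined = z.mean(axis=0)
    return gaussian_smooth(combined, window, bin_width)


def otsu_threshold(signal: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a 1-D signal.

    The signal is histogrammed into ``n_bins`` equal-width bins over
    ``[min, max]``; the returned threshold is the lower edge of the first
    supra-threshold class, chosen to maximize between-class variance.
    Deterministic; raises on a constant signal.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    lo, hi = signal.min(), signal.max()
    if lo == hi:
        raise ValueError("constant signal has no Otsu threshold")
    hist, edges = np.histogram(signal, bins=n_bins, range=(lo, hi))
    hist = hist.astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_mean = np.cumsum(hist * centers)
    grand = cum_mean[-1]
    w1 = total - w0
    # between-class variance for a cut after bin i (classes <= i, > i)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand - cum_mean) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv = np.where((w0 > 0) & (w1 > 0), bcv, -np.inf)
    cut = int(np.argmax(bcv[:-1]))  # last edge leaves class 1 empty
    return float(edges[cut + 1])


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_network_bursts(
    rec: SpikeRecording,
    params: NetworkBurstParams = NetworkBurstParams(),
) -> list[NetworkBurst]:
    """Detect (unclassified) network bursts in one well.

    Returns sorted, disjoint, bin-edge-aligned intervals. Raises if the well
    is entirely silent (no Otsu threshold exists).
    """
    counts, electrodes = bin_spikes(rec, params.bin_width)
    smoothed = np.vstack(
        [gaussian_smooth(c, params.gauss_window, params.bin_width) for c in counts]
    )
    combined = combine_standardized(smoothed, params.gauss_window, params.bin_width, electrodes)
    thr = otsu_threshold(combined, params.otsu_bins)

    n_electrodes = len(electrodes)
    need_participating = math.ceil(params.min_participation * n_electrodes)
    bursts: list[NetworkBurst] = []
    for a, b in _runs_above(combined > thr):
        start, end = a * params.bin_width, b * params.bin_width
        dur = end - start
        if dur <= params.min_duration:
            continue
        participating = []
        rates_ok = 0
        for e in electrodes:
            t = rec.spike_times[e]
            n_in = int(np.count_nonzero((t >= start) & (t < end)))
            if n_in > 0:
                participating.append(e)
                if n_in / dur >= params.min_rate:
                    rates_ok += 1
        if len(participating) < need_participating:
            continue
        if rates_ok < math.ceil(params.rate_fraction * len(participating)):
            continue
        bursts.append(
            NetworkBurst(start=start, end=end,
                         participating_electrodes=frozenset(participating))
        )
    return bursts


def classify_fragmented(
    bursts: Sequence[NetworkBurst],
    params: NetworkBurstParams = NetworkBurstParams(),
) -> list[NetworkBurst]:
    """Label each burst main or fragment, left to right.

    A burst of duration >= ``main_min_duration`` is a main burst. A shorter
    burst is a fragment if its gap to the preceding burst of its chain (or to
    the anchoring main burst when ``gap_to_main`` is set) is at most
    ``frag_max_gap`` and a main burst anchors the chain; otherwise it is
    classified main despite its short duration. Fragments carry the index of
    their anchoring main burst in the returned list.
    """
    out: list[NetworkBurst] = []
    last_main_idx: int | None = None
    chain_end: float | None = None  # end of the last burst eligible to extend a chain
    for b in sorted(bursts, key=lambda x: x.start):
        if b.duration >= params.main_min_duration:
            out.append(replace(b, klass="main", anchor=None))
            last_main_idx = len(out) - 1
            chain_end = b.end
            continue
        ref_end = (
            out[last_main_idx].end if (params.gap_to_main and last_main_idx is not None)
            else chain_end
        )
        if last_main_idx is not None and ref_end is not None and b.start - ref_end <= params.frag_max_gap:
            out.append(replace(b, klass="fragment", anchor=last_main_idx))
            chain_end = b.end
        else:
            # short but isolated: counts as a main burst of its own
            out.append(replace(b, klass="main", anchor=None))
            last_main_idx = len(out) - 1
            chain_end = b.end
    return out


def fragmentation_percentage(bursts: Sequence[NetworkBurst]) -> float:
    """Percent of classified network bursts labelled fragment; NaN if none."""
    if not bursts:
        return float("nan")
    n_frag = sum(1 for b in bursts if b.klass == "fragment")
    return 100.0 * n_frag / len(bursts)
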