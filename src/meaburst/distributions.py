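"""Network-burst-duration distributions and quantile-exceedance analysis.

Rather than comparing mean burst durations, whole distributions of individual
main-network-burst durations are pooled per experimental group and compared.
For acute-treatment experiments (e.g. picrotoxin block of GABA-A receptors)
the analysis derives a basal exceedance threshold: the largest group-wise
empirical 97.5th percentile of basal durations, guaranteeing that under basal
conditions fewer than 2.5% of events in every group exceed it. The percentage
of post-treatment events above that threshold then quantifies the unmasked
excitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from meaburst.network_bursts import NetworkBurst
from meaburst.spike_io import SpikeRecording

__all__ = [
    "DurationSample",
    "ExceedanceResult",
    "pool_durations",
    "basal_exceedance_threshold",
    "exceedance_fraction",
    "compare_duration_distributions",
    "firing_rate_change",
]


@dataclass
class DurationSample:
    """Pooled main-network-burst durations for one group/condition."""

    group: str
    condition: str  # basal | treated
    durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)

    @property
    def n(self) -> int:
        return int(self.durations.size)


@dataclass(frozen=True)
class ExceedanceResult:
    threshold: float
    basal_exceedance: dict[str, float]  # group -> percent, < 2.5 by construction
    treated_exceedance: dict[str, float]


def pool_durations(
    detections: Sequence[tuple[SpikeRecording, Sequence[NetworkBurst]]],
    group: str,
    condition: str = "basal",
) -> DurationSample:
    """Pool MAIN network-burst durations across a group's wells.

    Fragmented bursts are excluded. A group with no main bursts yields an
    empty sample with a warning.
    """
    durations = [
        b.duration
        for rec, bursts in detections
        if rec.metadata.get("group") == group
        for b in bursts
        if b.klass == "main"
    ]
    if not durations:
        warnings.warn(f"group {group!r}: no main network bursts to pool", stacklevel=2)
    return DurationSample(group=group, condition=condition,
                          durations=np.asarray(durations))


def _nearest_rank_quantile(x: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile: the ceil(q*n)-th order statistic."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    k = max(int(np.ceil(q * n)), 1)
    return float(x[k - 1])


def basal_exceedance_threshold(
    basal: Mapping[str, DurationSample] | Mapping[str, np.ndarray],
    tail: float = 0.025,
    pooled: bool = False,
) -> float:
    """Duration above which fewer than ``tail`` of basal events occur in every group.

    Default: the max over groups of the group-wise nearest-rank (1 - tail)
    quantile, which guarantees group-wise exceedance <= tail. ``pooled=True``
    instead takes the quantile of all basal durations pooled together.
    Raises if any group is empty.
    """
    arrays = {
        g: (s.durations if isinstance(s, DurationSample) else np.asarray(s, dtype=float))
        for g, s in basal.items()
    }
    if not arrays:
        raise ValueError("no basal groups supplied")
    for g, a in arrays.items():
        if a.size == 0:
            raise ValueError(f"basal group {g!r} is empty")
    if pooled:
        return _nearest_rank_quantile(np.concatenate(list(arrays.values())), 1 - tail)
    return max(_nearest_rank_quantile(a, 1 - tail) for a in arrays.values())


def exceedance_fraction(sample: DurationSample | np.ndarray, threshold: float) -> float:
    """Percent of durations strictly exceeding the threshold."""
    d = sample.durations if isinstance(sample, DurationSample) else np.asarray(sample, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    return 100.0 * float(np.count_nonzero(d > threshold)) / d.size


def compare_duration_distributions(
    sample_a: DurationSample | np.ndarray, sample_b: DurationSample | np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    Returns (standardized statistic, p value); delegated to the
    Mann-Whitney U machinery with normal approximation and tie correction,
    matching the classical rank-sum test with continuity correction.
    """
    a = sample_a.durations if isinstance(sample_a, DurationSample) else np.asarray(sample_a, float)
    b = sample_b.durations if isinstance(sample_b, DurationSample) else np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    # convert U to the standardized rank-sum statistic (z)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    ranks = stats.rankdata(np.concatenate([a, b]))
    tie_counts = np.unique(ranks, return_counts=True)[1]
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (res.statistic - mu - 0.5 * np.sign(res.statistic - mu)) / sd if sd > 0 else 0.0
    return float(z), float(res.pvalue)


def firing_rate_change(
    rec_pre: SpikeRecording, rec_post: SpikeRecording
) -> tuple[float, float]:
    """Well-level mean firing rate before and after an acute treatment.

    MFR = total spikes / (active electrodes x duration), an electrode being
    active with >=1 spike. A silent recording reports 0 Hz. Raises if the two
    recordings are from different wells.
    """
    if rec_pre.well_id != rec_post.well_id:
        raise ValueError(
            f"mismatched wells: {rec_pre.well_id!r} vs {rec_post.well_id!r}"
        )

    def mfr(rec: SpikeRecording) -> float:
        n_active = len(rec.active_electrodes())
        if n_active == 0:
            warnings.warn(f"well {rec.well_id!r}: no active electrodes", stacklevel=3)
            return 0.0
        return rec.total_spikes / (n_active * rec.duration)

    return mfr(rec_pre), mfr(rec_post)
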