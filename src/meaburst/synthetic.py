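"""Synthetic multiwell MEA recordings with ground-truth burst annotations.

Emulates the activity regimes of cultured neuronal networks on a multiwell
MEA: sparse background firing, synchronized network bursts recurring with a
controllable rate and inter-burst-interval variability, and optional
"fragmented" trailing bursts — short (< 0.32 s) events following a main burst
within 1.1 s, the signature of fragmented synchronization.

Generative model
----------------
Network-burst onsets follow a Gamma renewal process whose mean gap is
``60 / nb_rate`` seconds; the shape is ``1 / ibi_cov**2`` so the gap CoV is
controlled independently of the mean (scale = mean * ibi_cov**2). Burst
durations are log-normal. Within a burst, each electrode participates with
probability ``participation_prob`` and fires a homogeneous Poisson train at
``in_burst_rate`` Hz over the burst interval (boxcar profile; an exponential
decay profile is available but off by default). Background activity is an
independent Poisson train at ``background_rate`` Hz per electrode over the
whole recording. With probability ``frag_prob`` a main burst is trailed by a
Poisson-distributed number of fragments (mean ``frag_count_mean``, at least
one), each a short high-rate event whose gap to the previous burst of the
chain is drawn uniformly from ``frag_gap_range``.

Identical seeds give bit-identical recordings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

from meaburst.spike_io import PlateLayout, SpikeRecording

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_well", "simulate_plate",
           "simulate_development", "simulate_feature_table"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one experimental group.

    Rates are per-electrode Hz except ``nb_rate`` (network bursts per minute);
    durations and gaps are seconds.
    """

    background_rate: float = 0.3
    nb_rate: float = 6.0
    ibi_cov: float = 0.4
    nb_duration_mean: float = 0.6
    nb_duration_sd: float = 0.15
    participation_prob: float = 0.85
    in_burst_rate: float = 60.0
    frag_prob: float = 0.0
    frag_count_mean: float = 1.0
    frag_duration_range: tuple[float, float] = (0.12, 0.25)
    frag_gap_range: tuple[float, float] = (0.2, 0.9)
    duration: float = 300.0
    n_electrodes: int = 16
    sampling_rate: float = 12500.0
    seed: int = 0
    burst_profile: str = "boxcar"  # boxcar | exp_decay

    def __post_init__(self) -> None:
        if min(self.background_rate, self.nb_rate, self.in_burst_rate) < 0:
            raise ValueError("rates must be non-negative")
        for p in (self.participation_prob, self.frag_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.frag_duration_range
        if not (0.1 < lo <= hi < 0.32):
            raise ValueError("frag_duration_range must lie within (0.1, 0.32)")
        lo, hi = self.frag_gap_range
        if not (0 < lo <= hi <= 1.1):
            raise ValueError("frag_gap_range must lie within (0, 1.1]")
        if self.ibi_cov <= 0 and self.nb_rate > 0:
            raise ValueError("ibi_cov must be positive when bursts are generated")
        if self.burst_profile not in ("boxcar", "exp_decay"):
            raise ValueError(f"unknown burst_profile {self.burst_profile!r}")


@dataclass
class GroundTruth:
    """Planted intervals: the oracle the detectors are tested against."""

    #: (start, end, klass) per planted network burst, klass in {main, fragment}
    network_bursts: list[tuple[float, float, str]] = field(default_factory=list)
    #: electrode id -> list of (start, end) per planted electrode burst
    electrode_bursts: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def mains(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, k in self.network_bursts if k == "main"]

    def fragments(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, k in self.network_bursts if k == "fragment"]


def _quantize(t: np.ndarray, rate: float) -> np.ndarray:
    return np.round(t * rate) / rate


def _draw_burst_skeleton(cfg: SimulationConfig, rng: np.random.Generator
                         ) -> list[tuple[float, float, str]]:
    """Draw main-burst intervals plus fragments, rejecting overlaps.

    Returns (start, end, klass) sorted by start; raises after 1000 failed
    attempts to place a non-overlapping chain.
    """
    if cfg.nb_rate <= 0:
        return []
    mean_gap = 60.0 / cfg.nb_rate
    shape = 1.0 / cfg.ibi_cov**2
    scale = mean_gap * cfg.ibi_cov**2

    # log-normal parameters from desired mean/sd of the duration itself
    m, s = cfg.nb_duration_mean, cfg.nb_duration_sd
    sigma2 = np.log(1 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2

    intervals: list[tuple[float, float, str]] = []
    t = float(rng.gamma(shape, scale))  # first onset: one renewal gap from start
    while t < cfg.duration:
        for attempt in range(1000):
            dur = float(rng.lognormal(mu, np.sqrt(sigma2)))
            end = t + dur
            if end > cfg.duration:
                end = cfg.duration
            chain: list[tuple[float, float, str]] = [(t, end, "main")]
            if cfg.frag_prob > 0 and rng.random() < cfg.frag_prob:
                n_frag = max(1, int(rng.poisson(cfg.frag_count_mean)))
                prev_end = end
                ok = True
                for _ in range(n_frag):
                    gap = float(rng.uniform(*cfg.frag_gap_range))
                    fdur = float(rng.uniform(*cfg.frag_duration_range))
                    fs = prev_end + gap
                    fe = fs + fdur
                    if fe > cfg.duration:
                        ok = False
                        break
                    chain.append((fs, fe, "fragment"))
                    prev_end = fe
                if not ok and attempt < 999:
                    continue
            break
        else:
            raise RuntimeError("could not place a non-overlapping burst chain")
        intervals.extend(chain)
        chain_end = chain[-1][1]
        # next main onset: renewal gap from the end of this main burst;
        # re-drawn until it clears the fragment chain (keeps truth unambiguous)
        for attempt in range(1000):
            gap = float(rng.gamma(shape, scale))
            nxt = end + gap
            if nxt > chain_end + 0.05 or nxt >= cfg.duration:
                break
        else:
            raise RuntimeError("could not place the next burst onset clear of fragments")
        t = nxt
    return [iv for iv in intervals if iv[1] <= cfg.duration]


def _poisson_train(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_well(cfg: SimulationConfig) -> tuple[SpikeRecording, GroundTruth]:
    """Simulate one well; returns the recording and its planted ground truth.

    Spike times are quantized to the sampling grid and sorted per electrode.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = PlateLayout()
    electrodes = list(layout.electrode_ids[: cfg.n_electrodes])
    if cfg.n_electrodes > len(layout.electrode_ids):
        electrodes = [f"E{i}" for i in range(cfg.n_electrodes)]

    skeleton = _draw_burst_skeleton(cfg, rng)
    truth = GroundTruth(network_bursts=list(skeleton),
                        electrode_bursts={e: [] for e in electrodes})

    spikes: dict[str, list[np.ndarray]] = {e: [] for e in electrodes}
    for e in electrodes:
        spikes[e].append(_poisson_train(cfg.background_rate, 0.0, cfg.duration, rng))

    for start, end, _klass in skeleton:
        rate = cfg.in_burst_rate
        for e in electrodes:
            if rng.random() >= cfg.participation_prob:
                continue
            if cfg.burst_profile == "exp_decay":
                # thinning of a rate decaying to ~5% over the burst
                tau = (end - start) / 3.0
                cand = _poisson_train(rate, start, end, rng)
                keep = rng.random(cand.size) < np.exp(-(cand - start) / tau)
                train = cand[keep]
            else:
                train = _poisson_train(rate, start, end, rng)
            if train.size:
                spikes[e].append(train)
                truth.electrode_bursts[e].append((start, end))

    out = {}
    for e in electrodes:
        t = np.sort(np.concatenate(spikes[e])) if spikes[e] else np.empty(0)
        t = _quantize(t, cfg.sampling_rate)
        t = np.unique(t)  # quantization can collide background & burst spikes
        out[e] = np.clip(t, 0.0, cfg.duration)

    rec = SpikeRecording(
        well_id="A1",
        spike_times=out,
        duration=cfg.duration,
        sampling_rate=cfg.sampling_rate,
        metadata={"synthetic": True, "seed": cfg.seed},
    )
    return rec, truth


def simulate_plate(
    groups: Mapping[str, SimulationConfig],
    wells_per_group: int,
    seed: int = 0,
) -> tuple[list[SpikeRecording], dict[str, GroundTruth]]:
    """Simulate a plate with several experimental groups.

    Per-well seeds are derived deterministically from the master seed via a
    SeedSequence spawn, so the same master seed reproduces the plate exactly.
    Well ids follow the standard plate naming (A1, A2, ...).
    """
    if not groups:
        raise ValueError("at least one group is required")
    if wells_per_group == 0:
        warnings.warn("wells_per_group=0: returning an empty plate", stacklevel=2)
        return [], {}
    layout = PlateLayout()
    n_needed = len(groups) * wells_per_group
    if n_needed > len(layout.well_ids):
        raise ValueError(f"{n_needed} wells requested but the plate has {layout.n_wells}")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_needed)]

    recordings: list[SpikeRecording] = []
    truths: dict[str, GroundTruth] = {}
    i = 0
    for group, cfg in groups.items():
        for _ in range(wells_per_group):
            well_id = layout.well_ids[i]
            rec, truth = simulate_well(replace(cfg, seed=child_seeds[i]))
            rec.well_id = well_id
            rec.metadata.update({"group": group, "seed": child_seeds[i]})
            recordings.append(rec)
            truths[well_id] = truth
            i += 1
    return recordings, truths


def simulate_development(
    base: SimulationConfig,
    trajectory: Mapping[int, Mapping[str, object]],
    wells_per_div: int = 8,
    seed: int = 0,
) -> dict[int, tuple[list[SpikeRecording], dict[str, GroundTruth]]]:
    """Simulate one group across several recording days (DIVs).

    ``trajectory`` maps DIV -> overrides of SimulationConfig fields applied at
    that DIV; unknown field names are an error. Seeds differ per DIV but are
    derived deterministically from the master seed.
    """
    valid = {f.name for f in fields(SimulationConfig)}
    out: dict[int, tuple[list[SpikeRecording], dict[str, GroundTruth]]] = {}
    for div in sorted(trajectory):
        overrides = dict(trajectory[div])
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        cfg = replace(base, **overrides)
        recs, truths = simulate_plate({"base": cfg}, wells_per_div, seed=seed + div)
        for r in recs:
            r.metadata["DIV"] = div
        out[div] = (recs, truths)
    return out


def simulate_feature_table(
    seed: int = 0,
    n_rows: int = 600,
    n_noise: int = 6,
):
    """Synthetic feature table with planted variable and stable parameters.

    Emulates the structure the loading-based selection procedure is meant to
    recover from a wells x parameters table. Two pairs of *variable*
    parameters (``var_a1/var_a2`` and ``var_b1/var_b2``) share strong latent
    factors — one tied to a two-group design, one continuous — so after
    column scaling they dominate the first two principal components. Two
    pairs of *stable* parameters (``stable_a1/stable_a2``,
    ``stable_b1/stable_b2``) are moderately correlated within each pair
    (rho = 0.5) but carry no factor, so the pair-difference directions have
    the smallest eigenvalues and surface in the last retained components.
    ``n_noise`` independent unit-variance nuisance parameters fill the middle
    of the spectrum.

    Returns ``(table, planted_variable, planted_stable)`` where the sets name
    the planted columns.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    group = np.repeat([-1.0, 1.0], n_rows // 2)[:n_rows]
    factor_a = group + rng.normal(0, 0.3, n_rows)
    factor_b = rng.normal(0, 1.0, n_rows)
    cols = {
        "var_a1": factor_a + rng.normal(0, 0.3, n_rows),
        "var_a2": factor_a + rng.normal(0, 0.3, n_rows),
        "var_b1": factor_b + rng.normal(0, 0.3, n_rows),
        "var_b2": factor_b + rng.normal(0, 0.3, n_rows),
    }
    for pair in ("a", "b"):
        base = rng.normal(0, 1.0, n_rows)
        cols[f"stable_{pair}1"] = base
        cols[f"stable_{pair}2"] = 0.5 * base + np.sqrt(1 - 0.25) * rng.normal(0, 1.0, n_rows)
    for i in range(n_noise):
        cols[f"noise_{i + 1}"] = rng.normal(0, 1.0, n_rows)
    table = pd.DataFrame(cols)
    planted_variable = {"var_a1", "var_a2", "var_b1", "var_b2"}
    planted_stable = {"stable_a1", "stable_a2", "stable_b1", "stable_b2"}
    return table, planted_variable, planted_stable
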