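"""Independent reference implementations (oracles) and hand-derived values.

Shared by the unit suites and the acceptance suite; deliberately naive and
written without reference to the package's own implementations.
"""

import math

import numpy as np


def brute_force_bursts(times, max_isi, min_spikes, min_duration, merge_gap):
    """Independent literal application of the burst rules.

    Scan pairwise ISIs to form runs (ISI <= max_isi joins), merge runs whose
    gap is < merge_gap, then keep runs with >= min_spikes spikes and duration
    strictly > min_duration. Plain-Python reference, no vectorization.
    """
    times = list(times)
    runs = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] <= max_isi:
            j += 1
        runs.append((i, j))
        i = j + 1
    merged = []
    for run in runs:
        if merged and times[run[0]] - times[merged[-1][1]] < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    out = []
    for a, b in merged:
        n = b - a + 1
        if n >= min_spikes and (times[b] - times[a]) > min_duration:
            out.append((times[a], times[b], n))
    return out


def brute_force_otsu(signal, n_bins):
    """Naive Otsu: plain-Python loop over every histogram cut."""
    signal = np.asarray(signal, dtype=float)
    hist, edges = np.histogram(signal, bins=n_bins, range=(signal.min(), signal.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_bcv, best_cut = -1.0, None
    for cut in range(n_bins - 1):  # classes [0..cut], [cut+1..]
        w0 = sum(hist[: cut + 1])
        w1 = sum(hist[cut + 1:])
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(h * c for h, c in zip(hist[: cut + 1], centers[: cut + 1])) / w0
        mu1 = sum(h * c for h, c in zip(hist[cut + 1:], centers[cut + 1:])) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best_bcv:
            best_bcv, best_cut = bcv, cut
    return float(edges[best_cut + 1])


def oracle_classify(intervals, main_min=0.32, max_gap=1.1):
    """Literal left-to-right application of the fragmentation rule."""
    out = []  # (start, end, klass, anchor)
    last_main = None
    chain_end = None
    for s, e in sorted(intervals):
        if e - s >= main_min:
            out.append((s, e, "main", None))
            last_main = len(out) - 1
            chain_end = e
        elif last_main is not None and s - chain_end <= max_gap:
            out.append((s, e, "fragment", last_main))
            chain_end = e
        else:
            out.append((s, e, "main", None))
            last_main = len(out) - 1
            chain_end = e
    return out


def sd2(a, b):
    """Sample SD (ddof=1) of two values."""
    return abs(a - b) / math.sqrt(2)


def hand_expected_features():
    """All 39 parameters of the hand fixture, derived independently by hand.

    Primitive quantities (spike lists, burst intervals) are enumerated
    literally from the fixture definition; aggregates are computed with
    explicit arithmetic, never via the package.
    """
    # --- primitives, straight from the fixture layout ---------------------
    e1_isis = [0.05] * 4 + [9.8] + [0.1] * 5 + [79.5, 100.0]  # 12 ISIs
    e2_isis = [0.1] * 4 + [39.6, 100.0, 100.0]  # 7 ISIs
    e1_rate, e2_rate = 13 / 300, 8 / 300
    e1_inburst_isis = [0.05] * 4 + [0.1] * 5  # bursts A (5 sp) and B (6 sp)
    e2_inburst_isis = [0.1] * 4

    exp = {}
    # spike level
    exp["firing_rate_mean"] = (e1_rate + e2_rate) / 2
    exp["firing_rate_sd"] = sd2(e1_rate, e2_rate)
    exp["firing_rate_cov"] = exp["firing_rate_sd"] / exp["firing_rate_mean"]
    exp["total_spikes"] = 21.0
    exp["active_electrodes"] = 2.0
    exp["isi_mean"] = (np.mean(e1_isis) + np.mean(e2_isis)) / 2
    exp["isi_sd"] = (np.std(e1_isis, ddof=1) + np.std(e2_isis, ddof=1)) / 2
    exp["isi_cov"] = exp["isi_sd"] / exp["isi_mean"]
    # electrode-burst level: e1 has bursts [10.0,10.2]x5 and [20.0,20.5]x6,
    # e2 has [10.0,10.4]x5
    exp["eburst_rate"] = ((2 / 300) * 60 + (1 / 300) * 60) / 2
    exp["eburst_duration_mean"] = ((0.2 + 0.5) / 2 + 0.4) / 2
    exp["eburst_duration_sd"] = sd2(0.2, 0.5)  # e2 has one burst: no SD
    exp["eburst_duration_cov"] = exp["eburst_duration_sd"] / exp["eburst_duration_mean"]
    exp["eburst_isi_within_mean"] = (np.mean(e1_inburst_isis) + np.mean(e2_inburst_isis)) / 2
    exp["eburst_isi_within_sd"] = (np.std(e1_inburst_isis, ddof=1)
                                   + np.std(e2_inburst_isis, ddof=1)) / 2
    exp["burst_percentage_mean"] = (100 * 11 / 13 + 100 * 5 / 8) / 2
    exp["burst_percentage_sd"] = sd2(100 * 11 / 13, 100 * 5 / 8)
    exp["eburst_ibi_mean"] = 20.0 - 10.2  # e1's single gap; e2 has none
    exp["eburst_ibi_sd"] = float("nan")  # one gap: no SD anywhere
    exp["eburst_ibi_cov"] = float("nan")
    exp["spikes_per_eburst_mean"] = ((5 + 6) / 2 + 5) / 2
    exp["spikes_per_eburst_sd"] = sd2(5, 6)
    exp["bursting_electrodes"] = 2.0
    # network level: mains M1 [9.95,10.55] {e1,e2}, M2 [19.95,20.55] {e1}
    exp["nb_frequency"] = 2.0
    exp["nb_duration_mean"] = 0.6
    exp["nb_duration_sd"] = 0.0
    exp["nb_duration_cov"] = 0.0
    exp["nb_ibi_mean"] = 19.95 - 10.55
    exp["nb_ibi_sd"] = float("nan")  # single gap
    exp["nb_ibi_cov"] = float("nan")
    exp["network_burst_percentage"] = 100 * 16 / 21  # 10 spikes in M1 + 6 in M2
    exp["nb_participation_mean"] = (100.0 + 50.0) / 2
    exp["nb_participation_sd"] = sd2(100.0, 50.0)
    exp["nb_firing_rate_mean"] = (10 / (0.6 * 2) + 6 / (0.6 * 1)) / 2
    exp["nb_firing_rate_sd"] = sd2(10 / (0.6 * 2), 6 / (0.6 * 1))
    # fragmentation: F1 [21.0,21.2] anchored to M2
    exp["fragmentation_percentage"] = 100 / 3
    exp["fragment_duration_mean"] = 0.2
    exp["fragment_duration_sd"] = float("nan")  # single fragment
    exp["fragment_gap_mean"] = 21.0 - 20.55
    exp["fragments_per_main_mean"] = 0.5
    return exp

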