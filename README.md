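# meaburst

Network-activity analysis for multiwell micro-electrode-array (MEA)
recordings of cultured neuronal networks — the kind of data used to
phenotype patient-derived (iPSC) neurons across development.

Starting from spike timestamps, the package detects per-electrode bursts and
well-level *network bursts*, classifies *fragmented* network bursts (a
signature of pathological synchronization), extracts a 39-parameter
"network fingerprint" per well, isolates the parameters that vary — or
stay stable — across conditions via PCA loadings and UMAP, and compares
whole distributions of network-burst durations, including a quantile-based
exceedance analysis for acute-treatment experiments. A synthetic spike-train
generator with planted ground truth makes every stage verifiable without
patient data.

## The method in brief

* **Electrode bursts** — maximum-ISI algorithm: runs of spikes with
  inter-spike intervals ≤ 0.1 s, ≥ 5 spikes, duration > 0.05 s; runs closer
  than 0.05 s merge.
* **Network bursts** — spikes binned at 2 ms per electrode, smoothed with a
  70 ms Gaussian, z-scored, averaged across electrodes, re-smoothed; the
  combined signal is thresholded with Otsu's between-class-variance
  criterion. Intervals are kept if ≥ 25% of electrodes participate, the
  duration exceeds 0.1 s, and ≥ 25% of participating electrodes sustain
  ≥ 12 Hz inside the interval.
* **Fragmented bursts** — short network bursts (< 0.32 s) trailing a main
  burst by ≤ 1.1 s; counted separately as a fragmentation percentage.
* **Fingerprint** — PCA on the z-scored wells × parameters table; PCs with
  > 2.5% explained variance are kept and embedded with UMAP; the top-10
  |loading| parameters of the first/last retained PCs give the
  *variable*/*stable* parameter sets, intersected and differenced across
  datasets to isolate robust phenotype markers.
* **Duration distributions** — main-burst durations pooled per group; the
  basal exceedance threshold is the largest group-wise 97.5th percentile, so
  under basal conditions < 2.5% of events exceed it in every group; the
  post-treatment percentage above that threshold quantifies unmasked
  excitation (rank-sum tests for whole-distribution comparisons).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a two-group plate — a control group and a "mutant" group with rarer,
more irregular, fragmenting bursts — then detect and extract features:

```python
from meaburst import SimulationConfig, simulate_plate
from meaburst.pipeline import detect_all
from meaburst.electrode_bursts import ElectrodeBurstParams
from meaburst.network_bursts import NetworkBurstParams
from meaburst.features import aggregate_table

groups = {
    "control": SimulationConfig(duration=300.0),
    "mutant": SimulationConfig(duration=300.0, nb_rate=3.0, ibi_cov=0.6,
                               frag_prob=0.5),
}
recordings, truth = simulate_plate(groups, wells_per_group=4, seed=7)
detections = detect_all(recordings, ElectrodeBurstParams(), NetworkBurstParams())
table = aggregate_table(detections)
print(table.groupby("group")[["nb_frequency", "nb_ibi_cov",
                              "fragmentation_percentage"]].mean().round(2))
```

```
         nb_frequency  nb_ibi_cov  fragmentation_percentage
group
control         28.75        0.39                      3.55
mutant          13.75        0.58                     42.73
```

The control wells show ~29 network bursts per 5-minute recording with a
regular rhythm (IBI CoV 0.39 ≈ the planted 0.4) and almost no fragmentation;
the mutant wells burst half as often, more irregularly (CoV 0.58 ≈ the
planted 0.6), and 43% of their network bursts are fragments — the detected
phenotype matches what was planted.

The same analysis runs from the shell on a YAML config:

```sh
meaburst run-all --config examples/demo.yaml --seed 7 --out results/demo
```

with subcommands `simulate`, `detect`, `features`, `fingerprint`,
`exceedance` and `run-all`; outputs are plain CSV/JSON plus a run manifest
recording the package version, config hash and all seeds.

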