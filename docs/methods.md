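# Methods

This note documents the models and procedures implemented in `meaburst`, the
choices made where conventions were genuinely open, and what the synthetic
generator does and does not emulate.

## Input model

The pipeline starts from spike timestamps, not raw voltage. A recording is a
well on a 48-well micro-electrode array (MEA) plate, 16 electrodes per well in
a 4×4 grid (50 µm diameter, 350 µm pitch), sampled at 12.5 kHz for 5 minutes.
Times are seconds from recording start; every interval in the package is
half-open `[start, end)`. The canonical interchange format is a plain CSV
(`well_id, electrode_id, time_s`) plus a YAML manifest carrying duration,
sampling rate, each well's electrode list and its metadata (cell line, DIV,
group, treatment). Vendor binary formats and spike detection from voltage
traces are out of scope.

## Electrode burst detection (maximum-ISI)

A burst is a run of consecutive spikes whose inter-spike intervals (ISIs) are
all ≤ 0.1 s, containing at least 5 spikes and lasting strictly longer than
0.05 s; runs separated by a gap < 0.05 s are merged. The processing order is
**group → merge → filter**: merging first lets physiologically contiguous
firing that straddles a brief pause pass the 5-spike filter, which is the
point of the merge rule. The order is isolated behind a
`filter_before_merge` flag for sensitivity checks. Boundary conventions: an
ISI exactly equal to the maximum joins the burst (≤); a gap exactly equal to
the merge threshold does not merge (<). Burst start/end are the first/last
spike times, unpadded. Note that at the default parameters the merge rule
cannot fire (runs only split at gaps > 0.1 s > 0.05 s); it becomes active
when `merge_gap` is raised above `max_isi`, and the implementation therefore
places no ordering constraint between the two.

## Network burst detection

1. **Binning.** Spikes are binned per electrode at 2 ms; a spike exactly on a
   bin edge belongs to the later bin.
2. **Smoothing.** Each binned train is convolved with a unit-sum truncated
   Gaussian of 70 ms total support. "Window size" is read as total support
   (±3σ), so σ = window/6 ≈ 11.7 ms; the kernel spans 35 bins at defaults.
   Ends are reflect-padded so output length equals input length and a
   constant signal is unchanged.
3. **Combination.** Each electrode's smoothed signal is z-scored over the
   whole recording (zero-variance electrodes dropped, logged), the z-scores
   are averaged across electrodes — the mean rather than the sum, so the
   combined signal does not scale with electrode count — and the result is
   smoothed again with the same kernel.
4. **Thresholding.** The combined signal is thresholded with Otsu's
   between-class-variance criterion on a 256-bin equal-width histogram over
   `[min, max]`; the reported threshold is the upper edge of the lower class.
   Supra-threshold runs become candidate intervals, bin-edge aligned.
5. **Constraints.** A candidate is kept if (a) at least ⌈0.25 × n_electrodes⌉
   electrodes fire at least one spike inside it, (b) its duration exceeds
   0.1 s, and (c) at least ⌈0.25 × n_participating⌉ of the actively
   participating electrodes (≥1 in-interval spike) sustain an in-interval
   rate ≥ 12 Hz.

Whole-recording z-scoring (rather than a baseline segment) is assumed; all
smoothing and threshold conventions sit behind `NetworkBurstParams` for
sensitivity analysis.

## Fragmented network bursts

Short network bursts (< 0.32 s) that trail a main burst (≥ 0.32 s) by at most
1.1 s are classified as fragments and analysed separately; they may chain,
the gap being measured to the immediately preceding burst of the chain
(`gap_to_main=True` switches to measuring against the anchoring main burst).
Boundary ties: a duration of exactly 0.32 s is main; a gap of exactly 1.1 s
qualifies. A short burst with no qualifying predecessor counts as a main
burst of its own, and can itself anchor a chain. Fragmentation percentage is
100 × fragments / (fragments + mains).

## Feature catalogue (39 parameters)

Four tiers, all computable from one well's spikes plus its detections:
8 spike-level, 14 electrode-burst-level, 12 network-burst-level and
5 fragmentation-level parameters (see `meaburst.features` for the list). The
published supplementary definitions of the original 39-parameter set are not
reproduced verbatim; the catalogue here is the package's own, chosen to
cover the same tiers, and is config-driven (a YAML list of names) so an
alternative set can be swapped in without code change. The enumeration of
mean/SD/CoV companions in the electrode-burst tier yields 13 natural names;
the count of bursting electrodes was added as the 14th to complete the tier.

Conventions: well-level aggregates weight electrodes equally (not
spike-weighted); every CoV column equals its SD column divided by its mean
column; network-burst parameters use main bursts only ("IBI" in the network
tier is the end-to-start gap between consecutive main bursts — the
electrode-level IBI is a separate parameter); statistics requiring more
events than present are missing (NaN), never zero. Network burst frequency is
reported per 5-minute recording regardless of actual duration.

## Fingerprint analysis and parameter selection

Feature tables are z-scored per column (rows with missing values and
zero-variance columns dropped, logged), decomposed by SVD-based PCA with a
fixed sign convention (the largest-|loading| entry of each PC is positive),
and the PCs explaining strictly more than 2.5% of the variance are retained
(5% is the intended threshold for single-cell intrinsic-property tables).
UMAP (neighbors 15, min_dist 0.1, seeded) embeds the retained scores in 2-D.

Selection: the top-10 parameters by |loading| of each of the first two
retained PCs form the *variable* set; the top-10 of each of the last two
retained PCs form the *stable* set ("last" meaning last of the retained PCs,
consistent with the retention rule). Ties in |loading| break by catalogue
order, so selection is deterministic and row-order invariant. Stable sets
from multiple datasets are intersected; parameters contributing exclusively
to the stable PCs (never to the variable ones) are the robust,
condition-insensitive output; the complementary difference of variable sets
isolates parameters varying in one preparation but not another.

## Duration distributions and exceedance

Main-burst durations are pooled per group. The basal exceedance threshold is
the maximum over groups of the group-wise nearest-rank 97.5th percentile —
the max guarantees that under basal conditions at most 2.5% of events exceed
it in *every* group (a pooled-quantile mode is available behind a flag). The
nearest-rank estimator is used because it is deterministic and
interpolation-free. Post-treatment exceedance is the percentage of events
strictly above the threshold. In the synthetic treatment experiment,
exceedance percentages are evaluated on events pooled across groups: an
independent basal-distributed sample sits at the 2.5% boundary by
construction (the threshold is calibrated to exactly that tail), so pooling
is what gives the conservative max-over-groups threshold its margin.
Distribution comparisons use the two-sided Wilcoxon rank-sum test with
continuity correction (normal approximation, tie-corrected). Well-level mean
firing rate divides total spikes by active electrodes (≥1 spike) × duration.

## Synthetic generator

`simulate_well` emulates one well: network-burst onsets follow a Gamma
renewal process on the **end-to-onset** gap, with mean 60/`nb_rate` s and
shape 1/CoV² so the inter-burst-interval CoV — measured end-to-start, as the
feature extractor defines it — is controlled exactly and bursts can never
overlap. The cost of this convention is a realized burst frequency slightly
below `nb_rate` (the cycle length is gap + burst duration, ≈6% at defaults).
Burst durations are log-normal (mean 0.6 s, SD 0.15 s); each electrode joins
a burst with probability 0.85 and fires a homogeneous Poisson train at 60 Hz
inside it (boxcar profile; an exponential-decay profile is available but off
by default); background activity is Poisson at 0.3 Hz per electrode. With
probability `frag_prob`, a main burst trails max(1, Poisson(`frag_count_mean`))
fragments of duration 0.12–0.25 s at gaps of 0.2–0.9 s, satisfying the
fragment definition by construction; chains that would collide with the next
burst are re-drawn (capped at 1000 attempts). Spike times are quantized to
the sampling grid; identical seeds give bit-identical recordings, and plate-
and development-level wrappers derive per-well seeds from one master seed.

`simulate_feature_table` plants the structure the selection procedure is
meant to recover: two parameter pairs driven by strong latent factors (one
tied to a two-group design) that dominate PC1/PC2 after scaling, two
moderately correlated pairs (ρ = 0.5) whose pair-difference directions carry
the smallest eigenvalues and surface in the last retained PCs, plus
independent nuisance parameters. With 600 rows the sampling spread of the
nuisance eigenvalues (≈ [0.72, 1.32] by Marchenko–Pastur) stays clear of the
planted small eigenvalues (0.5), which still exceed the 2.5% retention
threshold.

What the generator does **not** emulate: biophysical membrane dynamics,
development of synchrony within a recording, electrode cross-talk, bursts
with internal temporal structure (by default), non-stationary background
rates, and the biological correlation structure among the 39 parameters.
Passing the recovery tests therefore shows the analysis chain is correct and
well-calibrated under the stated statistical assumptions, not that it is
robust to every property of real recordings.

## Problem sizes and numerical choices

Verification uses 5-minute, 16-electrode wells; oracle-equivalence checks run
on ≥1000 random parameterized instances (electrode bursts, fragment
classification) and ≥500 random signals (Otsu); planted-burst recovery uses
10 wells, parameter recovery 20 wells per condition, selection recovery 100
replicates of paired 600-row tables, and the treatment-effect experiment 50
replicates of 4 groups × 400 events. Detection recovers planted main bursts
with F1 ≈ 0.99 and mean boundary error ≈ 6 ms at the default 200× in-burst
rate contrast; with no planted fragments the detector still reports ≈1% of
bursts as fragments (one long burst occasionally splits into a main plus a
short trailing run), a property of adaptive thresholding rather than a
defect. Degenerate inputs are defined errors: entirely silent wells have no
Otsu threshold (pipelines log the well and continue with no bursts), and
constant signals, empty samples and empty groups raise with explicit
messages rather than returning placeholder values.
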