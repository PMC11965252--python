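# Methods

`neurodish` implements the analysis chain used to characterize the
electrophysiological maturation of neuronal cultures — typically
iPSC-derived glutamatergic neurons — at the network level (micro-electrode
arrays), the single-cell level (whole-cell patch clamp), and at the level
of iPSC genomic quality control (SNP-array probe preprocessing). Every
stage can be exercised on synthetic data with planted ground truth, so the
pipeline's recovery properties are testable without any recordings.

## MEA spike detection

Raw extracellular traces (16 electrodes per well, sampled at 12.5 kHz in
the emulated acquisition) are band-pass filtered at 200–3000 Hz with a
4th-order Butterworth filter applied forward–backward (zero phase, so
spike timestamps are not shifted; the acquisition convention names only
the cutoffs, the filter family and order are our choice). Spikes are
detected by hard thresholding at −k·σ̂ with k = 5. σ̂ is the baseline-noise
standard deviation; we estimate it with the scaled median absolute
deviation (1.4826·MAD) of the filtered trace rather than the raw SD, so
that the spikes themselves do not inflate the threshold — how the original
acquisition software segmented "baseline noise" is not documented, and the
robust estimator is the standard way to make the 5×SD rule
self-referential without bias. Detection is negative-going only
(extracellular convention; a bipolar mode exists behind a flag), the
timestamp is the most negative sample within a 1-ms dead-time window after
the crossing, and further crossings within the dead time are suppressed.
For band-limited Gaussian noise the expected rate of −5σ crossings is of
order 10⁻² per second (Rice's formula with an effective frequency of
~2 kHz), so false positives are negligible against the 0.1 spikes/s
activity criterion.

## logISI burst detection

A burst is a run of ≥ 5 consecutive spikes on one channel whose
inter-spike intervals (ISIs) all fall at or below a channel-specific
threshold. The threshold comes from the log-ISI histogram: bursting
channels show a bimodal distribution of log₁₀(ISI), with an intra-burst
mode at short ISIs and an inter-burst mode at long ones, and the threshold
is placed in the valley between them. Constants, all configurable on
`LogISIParams`:

| parameter | default | meaning |
|---|---|---|
| `bins_per_decade` | 10 | histogram resolution on the log₁₀ ISI axis |
| `smooth_bins` | 3 | moving-average window on the histogram |
| `isi_cap` | 100 ms | an intra-burst peak must sit at or below this ISI |
| `min_peak_fraction` | 0.1 | intra-burst peak height relative to the tallest peak |
| `void_threshold` | 0.7 | valley acceptance, v = 1 − h(min)/√(h(p₁)·h(p₂)) |
| `fallback_isi` | 100 ms | fixed cutoff when no valley passes the void test |

The search: find local maxima of the smoothed histogram; the intra-burst
peak is the tallest maximum at ISI ≤ `isi_cap` that also reaches
`min_peak_fraction` of the global maximum (this guard rejects stray
single-count bins in sparse, non-bursting trains — a homogeneous Poisson
train at 0.2 spikes/s over 8 minutes typically contains one or two
sub-100-ms ISIs that would otherwise register as a "peak"). The threshold
is the ISI at the first minimum between the intra-burst peak and a
subsequent peak whose void parameter reaches `void_threshold`; if an
intra-burst peak exists but no valley qualifies, the fixed `fallback_isi`
cutoff is used; if no intra-burst peak exists the channel gets no
threshold and hence no bursts. Trains with fewer than 3 spikes are never
burst-classified.

Channel metrics: MFR = N/duration (spikes/s); MBR = bursts/minute;
BD = mean burst duration (start/end = first/last spike, no padding);
RS = percentage of spikes outside all bursts. A channel is *active* when
MFR > 0.1 spikes/s and enters the bursting analysis when
MBR ≥ 0.4 bursts/min (the exclusion rule is stated as "lower than 0.4",
so an exactly-0.4 channel is included). RS of a silent channel is reported
missing rather than 0 or 100, to avoid biasing well averages.

## Network bursts

Single-channel bursts from all channels are chained in start-time order:
a burst joins the current cluster when the gap between the cluster's
running end and the burst's start is ≤ 100 ms (extent-gap chaining; the
source convention says only "consecutive bursts within a 100 ms window",
and chaining on extents rather than onsets is the interpretation that
makes overlapping bursts always cluster). A cluster is a network burst
when it recruits ≥ ceil(0.30 × n_eligible) distinct channels; with the
16-electrode well this is 5 channels. The denominator is the full array
by default (pass `n_eligible` explicitly to count against active channels
instead). NBR = network bursts per minute.

The population rate profile pools all spikes into uniform 10-ms bins
(spikes/s). Each network burst's peak is the profile argmax within the
event span, earliest bin on ties. For the aligned-burst view every event's
profile segment is centered on its own peak in a fixed window (0.5 s
before to 2 s after), which places all peaks — including the longest
event's — on the same reference column; the mean across events gives the
canonical steep-rise/slow-decay envelope.

## Patch-clamp features

Current clamp (steps Δ = 10 pA, 500 ms): an action potential is an upward
excursion whose rate of rise reaches 20 mV/ms and whose peak exceeds
0 mV; both constants are configurable (the criterion is ours — a standard
phase-plane choice — as the source analysis does not state one). The
per-AP threshold is the voltage where dV/dt first reaches the criterion
before the peak. Derived features: rheobase = smallest step current with
≥ 1 AP; AP amplitude = peak − threshold; AP width = full width at half
amplitude (half of peak − threshold, linearly interpolated at the
crossings); mean firing frequency at the 100-pA step = N/(t_N − t₁)
(taken literally as the ratio of the AP count to the first-to-last
interval; the (N−1)/(t_N − t₁) convention is available via a flag);
instantaneous firing frequency = 1/(t₂ − t₁). Frequencies are missing
when the reference sweep has < 2 APs. Spontaneous rate at the −40 mV
threshold potential = AP count / duration. Cells with access resistance
> 15 MΩ are flagged excluded.

Voltage clamp (steps −100 → +80 mV, Δ = 10 mV, 500 ms, holding −70 mV):
per step, the peak inward current is the most negative sample between
1 ms (capacitive-transient blanking) and 50 ms after step onset, and the
steady-state outward current is the mean over the last 10% of the step.
Densities J = I/C exactly (pA/pF), reported at the conventional −30 mV
(inward, Na⁺-like) and +80 mV (outward) steps. Inward values are clipped
at ≤ 0 and outward at ≥ 0 by sign convention.

## SNP-array preprocessing

Sequential probe exclusions, counted per filter in order: (1) sex
chromosomes X/Y/XY plus chromosomes 0 and MT (case-insensitive label
match); (2) position 0 (missing positions are treated as 0); (3) missing
R or BAF; (4) SNP type Indel or Deletion. Duplicated probe ids are then
collapsed: pairs take the mean of R and BAF, groups of more than two the
median (reading the "median (or mean) … more than two (equal to two)"
convention as mean-for-2 / median-for->2). Finally logR = γ·log₂(R) with
γ = 0.55; probes with R ≤ 0 cannot be transformed and are dropped with a
logged count. GC correction and allele-specific segmentation are
downstream tools' jobs; this module emits the table they consume.

## Statistics

Well aggregation: percent active electrodes uses 16 as denominator; MFR
averages over active channels, MBR/BD/RS over bursting-included channels,
NBR is well-level. Wells with fewer than 10 of 16 active electrodes at
the reference DIV are excluded before any comparison; the reference DIV
defaults to the timepoint of maximal mean MFR. Consecutive timepoints are
compared with the two-sided Wilcoxon signed-rank test on paired wells
(zero differences dropped; exact null for small tie-free samples, normal
approximation otherwise; < 3 informative pairs → degenerate, p = NaN),
and p-values are Benjamini–Hochberg adjusted across all comparisons
(statsmodels step-up). For two independent groups the test is chosen by
D'Agostino–Pearson normality of both groups (α = 0.05, requiring n ≥ 8
per group for a stable k² statistic): Student's t when both pass,
Mann–Whitney U otherwise. Trajectory tables report mean ± SD and SEM per
DIV with n = wells.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical regimes the pipeline must
classify, each with an explicit seed and a private RNG stream:

* **Poisson trains** — pre-bursting cultures; defaults 16 channels,
  0.2 spikes/s, 480 s (the 8-minute recording length).
* **Bursting trains** — bursts placed by a per-channel Poisson process
  (default 10/min), 8 spikes at 10-ms intra-burst ISI, on 0.05 spikes/s
  background; the intra-burst ISI must be ≤ 1/20 of the mean background
  ISI so the two ISI modes are separable. Colliding planted bursts are
  merged in the ground truth and counted once.
* **Network-bursting trains** — planted events recruit a random subset of
  round(participation × 16) channels with onsets jittered ≤ 20 ms; spike
  times within a burst follow an alpha-like rate envelope with rise
  (10 ms) ≪ decay (100 ms), giving the canonical population-burst shape.
  Planted events are kept temporally separated so ground-truth identity
  is unambiguous.
* **Raw traces** — band-limited (200–3000 Hz) Gaussian noise with a 1-ms
  biphasic, negative-dominant spike template added at each spike time;
  default amplitude 8 noise-SD.
* **Current-clamp families** — RC subthreshold responses below the
  planted rheobase; stereotyped APs above it (threshold −40 mV, peak
  +30 mV), with a slow 10 mV/ms approach from baseline to threshold so
  that a dV/dt-criterion detector recovers the planted threshold, as real
  subthreshold depolarization precedes spike initiation.
* **Voltage-clamp families** — fast-inactivating inward transient peaking
  2 ms after onset plus sustained outward plateau, a 0.3-ms capacitive
  transient, and 5 pA current noise. The inward kernel is rescaled so the
  planted value is the *net* peak inward current (what the measurement
  reads), compensating overlap with the rising outward current. The
  default density profile peaks at −305.6 pA/pF at −30 mV, the magnitude
  reported for mature glutamatergic neurons.
* **Probe tables** — clean autosomal probes plus planted probes failing
  exactly one filter each and duplicated ids in pairs and triples.

What the synthetic data does **not** emulate: spike-waveform diversity
and overlap (no sorting is attempted), electrode cross-talk, slow drifts
and artifacts, biophysical (conductance-based) membrane dynamics, leak
and series-resistance errors in voltage clamp, GC-content waves or
allelic imbalance structure in probe intensities. Passing recovery tests
therefore demonstrates the correctness of the algorithms under their
stated assumptions, not robustness to every pathology of real recordings.

## Problem sizes and numerical choices

Test and example workloads are sized for interactive runs: recovery tests
use 8-minute, 16-channel spike-train wells; raw-trace detection uses 8
channels × 60 s at 12.5 kHz; patch recovery uses 50 randomized cells;
oracle cross-checks use 1000 random trains (≤ 200 spikes) against an
O(n²) run-finder, 1000 random p-vectors against a brute-force BH
step-up (tolerance 1e-12), and exhaustive 2ⁿ sign enumeration for the
exact Wilcoxon p at n ≤ 10. Histogram bin edges are aligned to whole
bins of the log scale; spikes exactly on a rate-profile bin edge follow
NumPy's half-open convention (the final edge is inclusive). Ties at a
profile peak resolve to the earliest bin. Coincident synthetic spikes
(< 1 ns apart) are deduplicated to keep trains strictly increasing.

## Known limitations

* The logISI constants are implementation defaults, not values fixed by
  the emulated acquisition system; cross-software comparisons should
  calibrate them.
* Burst-extent chaining can bridge two genuinely distinct network events
  if the well's inter-event intervals approach the 100-ms window.
* The exact Wilcoxon path requires tie-free |differences|; with ties the
  normal approximation is used, as in standard implementations.
* `detect_spikes` assumes the input is already band-passed; running it on
  raw traces inflates σ̂ and loses sensitivity.
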