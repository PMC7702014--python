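# Methods

`szjitter` quantifies how similar spontaneous seizure-like events are to one
another in chronic in vitro local field potential (LFP) recordings — e.g.
organotypic hippocampal cultures, which become spontaneously epileptic after
about a week in vitro — and how that similarity evolves over hours. Its core
is a timing statistic ("jitter") on the inter-spike intervals of the
population spikes that make up each seizure. This note documents the models,
estimators, defaults and their rationale, and what the bundled synthetic
generator does and does not establish.

## Signal model and preprocessing

A recording is a uniformly sampled voltage trace (volts internally; file
units are converted at the boundary). Typical rates are 5–6 kHz. Filtering
presets follow standard practice for these preparations:

* `mea_notch` — 4th-order Butterworth band-stop 58–62 Hz (mains).
* `mea_highpass` — 4th-order Butterworth high-pass at 3 Hz (DC and slow
  mechanical drift).
* `smw_band` — 4th-order band-pass 1 Hz–min(3 kHz, 0.45·rate).

All filters run **zero-phase** (forward–backward). Jitter is a timing
statistic; one-pass IIR filtering would delay spike peaks by a
frequency-dependent amount and bias it. The cost is that the effective
magnitude response is the square of the designed filter's; the stated order
refers to the designed prototype. Whether the analyses this package models
were originally run zero-phase is not known; the choice is flagged here
deliberately.

Downsampling (e.g. 6 kHz → 1 kHz for storage or speed) uses polyphase FIR
resampling, which is also zero-phase and therefore does not shift peaks
systematically. The acceptance script verifies that the entire
detection + jitter pipeline changes by well under 10 % of the jitter value
under a 6 kHz → 1 kHz rerun.

## Population-spike detection

A dual-threshold rule on the rectified trace: a candidate spike is an
excursion that starts below the lower threshold (default 0.5 mV), exceeds
the upper threshold (default 1 mV) and returns below the lower threshold
within 5–150 ms; its time is the absolute peak. Two candidate peaks within
the 100 ms refractory period are counted as one **biphasic** spike at the
larger peak (ties keep the earlier). Rectification makes detection invariant
to trace polarity — population spikes can be negative-going depending on
electrode position.

Interactive spike curation is replaced by an override table: event rows
that add a spike at a stated time or remove the nearest detected spike,
applied after automatic detection, so corrections are reproducible.

## Seizure segmentation

Seizures are paroxysmal events: runs of 0.5 s bins whose peak amplitude
exceeds a raster threshold, lasting ≥ 10 s, with a within-event discharge
rate ≥ 2 Hz. Sub-threshold gaps ≤ 2 s (`gap_tol_s`) are bridged, since
intervals between late-seizure spikes can exceed one bin.

Two estimator choices deserve explanation:

* **Raster threshold.** The threshold is "a few tens of microvolts above
  background" (default offset 40 µV, validated against a 20–65 µV range).
  The background term is the **median per-bin peak amplitude** of the
  trace, not its standard deviation: a 0.5 s bin at 6 kHz holds 3000
  samples, so the expected *peak* of pure Gaussian background sits ~4 σ
  above the σ-scale, and an offset defined relative to σ would fire on
  every noise bin. The σ-scale estimator (MAD × 1.4826 with event
  exclusion) is still provided (`estimate_background`) for SNR-style
  uses. The median-of-bin-peaks estimator assumes paroxysmal activity
  occupies a minority (< 50 %) of bins. An explicit threshold can always
  be passed instead.
* **Discharge rate.** The ≥ 2 Hz rule counts super-threshold excursions
  *after* biphasic merging (peaks within 100 ms count once). Without
  merging, each biphasic spike contributes two excursions and a 1 Hz
  spike train would pass a 2 Hz criterion.

## The jitter statistic

Two seizures are compared through their inter-spike-interval sequences.
Given one alignment spike in each train, intervals are indexed by signed
offset from the alignment spike and paired at offsets present in both
trains:

    jitter = (100 / n) * Σ_i |I1_i − I2_i| / ((I1_i + I2_i) / 2)   [%]

The reported value is the **minimum over all alignment-spike pairs**, which
makes the statistic invariant to global time shifts and to which spike a
seizure "starts" with; because each term is a normalized difference it is
also scale-invariant and bounded by 200 %. Because a time error on one
spike perturbs only the two intervals it borders, the statistic is robust
to isolated timing errors in a way cumulative phase measures are not.

Implementation: the set of paired intervals at alignment (i₁, i₂) depends
only on i₂ − i₁, so the exhaustive minimization reduces to minimizing the
mean of each diagonal of the normalized-interval-difference matrix —
O(n²) rather than O(n³). Tests check this against a naive brute-force
enumeration. Interval pairing extends in both directions from the
alignment spike by default (`pairing="signed"`); a forward-only variant is
available since the original formulation leaves the direction open. With
alignment at the first spikes, both reduce to pairing the i-th intervals
and `n` is the interval count of the shorter seizure.

Seizures with fewer than two spikes cannot form intervals; they are
flagged as missing (NaN rows in the pairwise matrix), never silently
dropped.

## Jitter evolution and state transitions

The windowed jitter trace assigns each seizure to windows by onset time
(default 1 h window, 10 min step) and takes the mean pairwise jitter over
all unique pairs in the window (the averaging rule is not prescribed
anywhere; all-pairs is the symmetric choice). Windows with fewer than two
seizures are missing. For short recordings an event-count window
(`events_per_window`, default 2, advanced one event per step) is the
natural alternative, summarized into 5 min box-plot bins by `bin_trace`.

**State transitions** — transient reorganizations of the seizure waveform —
are called where the trace exceeds its own mean + k·SD (default k = 2,
sample SD over the recording's non-missing windows). Maximal runs of
consecutive super-threshold windows form one event; missing windows break
runs; a constant trace (SD = 0) has no transitions by definition. Every
window *containing* a waveform change is elevated, so the first
super-threshold window start is biased early by up to one window length;
the unbiased point estimate of the transition time is the event midpoint
(`TransitionEvent.time_s`), which is what the synthetic recovery tests
score (recovery within one step, 600 s).

Within-state vs cross-state comparisons take pairwise jitters inside each
inter-transition segment vs across adjacent segments; seizures during a
transition span belong to no state.

Dispersion summaries use the sample (n−1) variance throughout: Fano factor
= sample variance / mean, applied to seizure durations and inter-seizure
intervals; the jitter–variability correlation is a Pearson r between the
windowed jitter and the windowed SD of durations (or onset intervals),
with pairwise deletion of missing windows.

## Calcium ΔF/F insertion analysis

Input is per-ROI mean-intensity traces (~5 samples/s). The baseline F0 is
estimated by asymmetric least squares (ALS): iteratively reweighted
penalized least squares with a second-difference penalty (stiffness λ) and
asymmetry p (default 0.01, 10 iterations) — points above the current
baseline get weight p, points below 1−p, so positive transients ride above
the fit while linear drift (unpenalized by second differences) is
recovered exactly. Default λ = 1e5 suits transients of seconds to tens of
seconds at 5 Hz.

The electrode-insertion transient is different: it lasts ~10³ s
(thousands of samples), and **no practical stiffness keeps it entirely
above the fit** (λ ≥ 1e14 is also numerically fragile in double
precision). Since the insertion time is known, `insertion_dff` excludes
`[event, event + 1800 s)` from the affected ROI's baseline fit
(near-zero weights; the penalty bridges the gap smoothly) and uses
λ = 1e10 so the bridge's boundary slopes are stable. The reference ROI is
baselined normally, ΔF/F = (F−F0)/F0 is formed for both, and the
reference is subtracted to remove culture-wide spontaneous activity.

Recovery time is the first time after the post-event peak at which
|ΔF/F| ≤ 2 % of baseline **sustained for 60 s** (single noise crossings do
not count; a sub-threshold run reaching the end of the trace counts).
Under noise this estimator is effectively a last-exceedance time and is
biased late for a single trace; measuring it on the insertion-aligned
average of ≥ 3 replicate preparations (mirroring how such experiments are
summarized) suppresses that bias. The synthetic insertion model programs a
rise to peak in ~20 s and decay back within 2 % by ~900 s and verifies the
full pipeline recovers the programmed value within 10 %.

## Synthetic generator

Everything above is validated against a seeded generator
(pure function of config + seed, byte-identical reruns):

* **Templates.** Abrupt-onset: 60 spikes / 20 s (3 Hz), intervals ramping
  0.15 → 0.53 s, first spike 1.5 mV then 1.2 mV — the "large first spike,
  slowing discharge" morphology. Ramping: 60 spikes / 25 s, parabolic
  interval profile (fast middle), amplitudes swelling 1.2 → 1.5 → 1.2 mV.
* **Spike kernel.** 20 ms biphasic: 8 ms positive half-sine main lobe and
  a 12 ms opposite lobe at 0.9 relative amplitude. The opposite lobe of a
  ≥ 1.2 mV spike crosses the 1 mV upper threshold, so every rendered spike
  exercises the biphasic-merge rule; the sharp 8 ms main lobe keeps the
  peak-time error from 20 µV noise below one sample.
* **Timing noise.** Per-spike i.i.d. Gaussian, default σ = 5 ms, re-sorted
  with the 0.1 s minimum separation enforced by rejection. Expected
  measured jitter grows monotonically with σ (verified at 1–25 ms).
* **Placement.** Explicit onset lists, or gamma-distributed inter-seizure
  intervals (mean 300 s, CV 0.3 — such cultures seize every few minutes);
  events are kept disjoint. Background noise 20 µV RMS. Scheduled template
  switches and timing-noise schedules emulate spontaneous state
  transitions and media-exchange-like perturbations.
* **Calcium.** Shared baseline, linear drift, sparse positive common-mode
  bursts (~every 45 s, ~3 % ΔF/F, 6 s decay — spontaneous culture-wide
  events), ROI-mean noise 0.2 % of baseline, and the insertion transient
  above. Truth (exact programmed recovery) is scanned from the noiseless
  shape on a 10 ms grid.

What a green synthetic test establishes: the estimators recover the
quantities the generator programmed, at realistic amplitudes, rates and
noise levels, through the full render → filter → detect → analyze loop.
What it does not: robustness to electrode drift, non-stationary noise,
overlapping or multifocal events, waveform shapes outside the two template
families, or optical artifacts (bleaching is a linear drift here; real
bleaching is not).

## Numerical notes and edge cases

* Event times are half-open `[start, end)` seconds; spikes are instants;
  0-based sample indexing; sample k is at `t0 + k/rate`.
* Jitter alignment ties break toward the lexicographically smallest index
  pair; equal biphasic peaks keep the earlier.
* EDF output is 16-bit quantized over a per-channel physical range
  (ASCII-serialized, slightly widened so truncation cannot overflow the
  digital range); CSV is lossless and is the reference format.
* `detect_seizures` on an empty or quiescent trace returns an empty list,
  not an error; `fano` requires ≥ 2 values and positive mean;
  `recovery_time` raises if the trace never exceeds the 2 % band (no
  event-locked transient to time).
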