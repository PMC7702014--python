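# szjitter

Seizure-waveform **jitter** analysis for in vitro local field potential
(LFP) recordings.

Chronic slice models of epilepsy — organotypic hippocampal cultures in
particular — produce spontaneous seizure-like events for weeks, and the
*variability* of those events limits experimental throughput: frequency and
duration alone are blunt instruments for deciding whether a preparation is
stable, perturbed, or reorganizing. `szjitter` implements a sharper
similarity measure on the timing of the population spikes that make up each
seizure, and the analysis stack around it:

* preprocessing (zero-phase Butterworth presets, anti-aliased
  downsampling, SNR),
* dual-threshold population-spike detection with biphasic-spike merging,
  and raster-based seizure segmentation (≥ 10 s, ≥ 2 Hz paroxysmal events),
* the **jitter statistic**: for two seizures with inter-spike-interval
  sequences I¹, I², aligned at one spike per seizure,

  ```
  jitter = (100 / n) · Σᵢ |I¹ᵢ − I²ᵢ| / ((I¹ᵢ + I²ᵢ)/2)    [percent]
  ```

  minimized over all alignment-spike pairs (shift- and scale-invariant,
  bounded by 200 %),
* sliding-window jitter evolution (1 h window / 10 min step) with
  mean + 2 SD calling of spontaneous **state transitions**, within- vs
  cross-state comparisons, Fano factors of durations/intervals and
  jitter–variability correlations,
* calcium ΔF/F analysis of electrode-insertion damage (asymmetric least
  squares baseline, reference-ROI subtraction, insertion-aligned
  averaging, 2 %-of-baseline recovery time),
* a fully seeded synthetic generator (seizure templates, spike-timing
  noise, state schedules, insertion transients) providing ground truth for
  every stage.

## Worked example

```python
import numpy as np
from szjitter import (SimConfig, simulate_recording, DetectParams,
                      detect_seizures, jitter, pairwise_jitter, fano)

cfg = SimConfig(duration_s=300.0,
                seizure_times_s=[20.0, 80.0, 140.0, 200.0, 255.0],
                seed=1)
rec, truth, _ = simulate_recording(cfg)       # 6 kHz, 1.2 mV spikes, 20 µV noise
seizures = detect_seizures(rec, DetectParams())
print(f"{len(seizures)} seizures detected")
for s in seizures:
    print(f"  {s.start_s:7.1f}-{s.end_s:6.1f} s  {len(s.spikes):3d} spikes  "
          f"{s.mean_event_rate_hz:.2f} Hz")
res = jitter(seizures[0].spikes, seizures[1].spikes)
print(f"jitter(sz0, sz1) = {res.jitter_pct:.2f} % over {res.n_interval} intervals")
m = pairwise_jitter(seizures)
print(f"mean pairwise jitter: {np.mean(m[np.triu_indices(5, 1)]):.2f} %")
```

prints

```
5 seizures detected
     19.5-  40.5 s   60 spikes  2.86 Hz
     79.5- 100.5 s   60 spikes  2.86 Hz
    139.5- 160.5 s   60 spikes  2.86 Hz
    199.5- 220.5 s   60 spikes  2.86 Hz
    254.5- 275.5 s   60 spikes  2.86 Hz
jitter(sz0, sz1) = 2.32 % over 59 intervals
mean pairwise jitter: 2.54 %
```

All five programmed seizures are recovered with every spike (60 each)
inside the stated bounds; five renderings of the same template with 5 ms
per-spike timing noise differ by ~2.5 % jitter — similar waveforms, small
timing scatter. Two seizures from *different* templates typically sit at
30–80 % jitter, which is what makes the statistic useful for spotting
waveform reorganizations: a sliding-window jitter trace spikes above its
mean + 2 SD exactly when the culture switches waveform state
(`windowed_jitter` → `detect_transitions`).

## Command line

```bash
szjitter simulate  --config sim.yaml --out rec.csv --truth truth.csv
szjitter filter    --preset mea_notch --preset mea_highpass --in rec.csv --out f.csv
szjitter detect    --in f.csv --out events.csv
szjitter jitter    --events events.csv --out jitter.csv
szjitter evolve    --events events.csv --window 3600 --step 600 --out trace.csv
szjitter transitions --trace trace.csv --k 2 --out transitions.csv
szjitter dff       --in roi.csv --ref roi_ref.csv --out dff.csv
szjitter pipeline  --in rec.csv --out results/
```

`pipeline` chains filter → detect → jitter → evolve → transitions and
writes `events.csv`, `jitter_matrix.csv`, `trace.csv`, `transitions.csv`
and a `report.json` (seizure count, duration/interval Fano factors,
transition count, resolved config).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the robustness of the jitter statistic to
downsampling: ten 6 kHz recordings of five noisy template seizures each are
simulated, the full detection + jitter pipeline is run, each recording is
downsampled to 1 kHz and rerun, and the maximum relative change across all
seizure pairs is reported (in percent).

See `docs/methods.md` for the estimator definitions, defaults and their
rationale, and the limits of what the synthetic validation establishes.
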