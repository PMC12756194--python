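# Methods

This note documents the models, parameter choices and numerical decisions
behind `biovolt`, in the order data flows through the package.

## Signal model

A recording day is modelled as the exact sample-wise sum of four components,
all in microvolts at sampling rate `fs_hz` (default 2000 Hz — ten samples
across a 5 ms pulse, 7.2 M samples per hour):

1. **Fast spikes.** Event times are a homogeneous Poisson process at
   `rate_per_min / 60` s⁻¹. Each event is a Gaussian-bell pulse whose full
   width (`width_ms`, default 5 ms) is taken as the ±3σ extent of the bell;
   no waveform at sample resolution is established for these signals, so a
   smooth unimodal template is the weakest assumption that fixes the two
   quantities the readout uses, amplitude and width. Peak amplitudes are
   log-normal with median `amp_median_uv` and log-scale s.d. `amp_spread`
   (right-skewed amplitude summaries rule out a symmetric law); polarity is
   positive with probability `polarity_prob_pos` (default 0.5 — polarity
   depends on electrode wiring and detection ignores it). Overlapping pulses
   sum.
2. **Telegraph (RTS) component.** A two-state Markov process: level 0 (low)
   and `step_uv` (high), exponential dwells with rates `k_up` (low→high) and
   `k_down` (high→low), started low, dwells quantized to ≥ 1 sample. A zero
   rate makes its state absorbing.
3. **Noise.** White Gaussian (`white_sd_uv`), 1/f Gaussian (`pink_sd_uv`,
   white noise shaped by f^(−1/2) in the frequency domain, zero DC, rescaled
   to the target s.d.; periodogram slope ≈ −1 over 0.01–10 Hz) and a
   deterministic linear ramp (`drift_uv_per_min`). With all three zero the
   component is identically zero.
4. Nothing else: the generated trace equals spikes + telegraph + noise
   exactly, which the tests assert bit-wise.

**Determinism.** `synthesize_schedule(schedule, fs, seed)` derives one
`numpy.random.SeedSequence(seed, spawn_key=(condition_index, stream))` per
condition and stream (0 = spikes, 1 = telegraph, 2 = noise), so any single
condition is reproducible without generating the others.

## Calibration of the default schedule

The default six-condition schedule encodes a four-day nitrogen-starvation
course followed by two days after ammonium addition, with per-day targets
taken from the published summary table (per-minute rate and amplitude
quartiles per day):

| condition | day | rate (min⁻¹) | amp Q2 (µV) | amp IQR (µV) | k_up (s⁻¹) | k_down (s⁻¹) |
|-----------|-----|--------------|-------------|--------------|------------|--------------|
| -Nd1      | 1   | 1            | 3.5         | 2.6–5.0      | 0.05       | 0.5          |
| -Nd2      | 2   | 2            | 3.7         | 2.7–5.2      | 0.05       | 0.5          |
| -Nd3      | 3   | 1            | 6.0         | 3.8–9.2      | 0.10       | 0.5          |
| -Nd4      | 4   | 5            | 6.0         | 3.7–9.4      | 0.10       | 0.5          |
| NH4+d1    | 5   | 3            | 3.6         | 2.5–5.2      | 0.05       | 0.5          |
| NH4+d2    | 6   | 1            | 4.7         | 3.0–6.5      | 0.03       | 0.5          |

- The spike rate equals the day's published rate median (the Poisson median
  essentially equals its rate at these values). Day 3 follows the table row
  (median 1 min⁻¹) rather than the accompanying prose ("5 events min⁻¹ on
  days 3 and 4"); the two cannot both hold and the table is the primary
  record.
- `calibrate_amplitude(q2, iqr_lo, iqr_hi, q4)` maps published quartiles to
  log-normal parameters: the median is matched exactly and the log-spread is
  the least-squares fit of the inner quartiles on the log scale, closed form
  `ln(iqr_hi/iqr_lo) / (2 z₀.₇₅)`. Q4 is treated as the observed maximum of
  the published sample, not a distribution parameter (a rate Q4 of 82 at a
  median of 5 is only consistent with a maximum), so it is validated but not
  fitted.
- The telegraph step is set to the day's amplitude median, so the pooled
  (spike + step) amplitude distribution keeps its median on the day's target
  regardless of the class mix. Telegraph kinetics keep the high-state dwell
  mean at 1/k_down = 2 s (the "seconds" class) and modulate excursion
  frequency across the course: starvation days 3–4 are the most active,
  repletion day 2 the quietest.
- Noise defaults: white 0.3 µV, pink 0.5 µV, drift 0.5 µV/min. The white
  floor puts a 3.5 µV spike at ~8σ of the fast band so most of the amplitude
  law clears a 5σ threshold while the floor stays in the "low-noise,
  tens-of-µV signals" regime; the pink component lives almost entirely in
  the slow band.
- Per-condition duration defaults to 3600 s (any duration ≥ 60 s is accepted
  at analysis time).

## Detection pipeline

- **Baseline.** Running median, window 60 s (≥ 10× the dwell scale so steps
  are not absorbed; ≥ 3 samples enforced). The median is evaluated on a
  ~20 Hz decimated grid and linearly interpolated back — the baseline varies
  on the minutes scale, so this changes nothing but the cost. The window is
  forced to an even sample count: an even-count median interpolates between
  the two central order statistics, which keeps the baseline *between* the
  levels of a two-state signal even at 50% duty, where an odd-count median
  snaps to whichever level holds the majority and can double the apparent
  step. The detrended trace is recentred to zero median.
- **Band split.** f_c = 10 Hz, two octaves from both classes (≤ 50 ms pulses
  vs ≥ 0.5 s dwells). Zero-phase (forward–backward) 4th-order Butterworth
  high-pass gives the fast band without biasing peak times (< 1 sample
  shift) or amplitudes; the slow band is the exact complement, so
  reconstruction is exact rather than approximate.
- **Threshold.** k = 5 on σ = 1.4826 × MAD of the fast band. MAD ignores the
  spikes themselves (1% contamination by 50 µV events moves the estimate by
  < 5%) and any constant offset; 5σ keeps the false-event rate on pure noise
  below 0.2 min⁻¹ at 2 kHz (verified by simulation). Refractory merging:
  supra-threshold runs whose gap is ≤ 20 ms form one event.
- **Segmentation.** Operates on the slow band decimated to ≤ 200 Hz (dwell
  floor 0.5 s ⇒ quantization error < 0.5% of the shortest admissible dwell);
  the mixture is fit on at most 50 000 strided samples with means
  initialized at the 25th/99th percentiles and a fixed random state, so the
  fit is deterministic and finds a minority high state down to ~2%
  occupancy. Degeneracy ("no RTS") is declared model-based: the two-level
  fit must beat a single Gaussian by BIC *and* the levels must sit ≥ 2
  within-level sigmas apart (the bimodality threshold for a two-Gaussian
  mixture). Band-level scale statistics are unusable here: at high telegraph
  duty they include the step itself and would veto a real signal. Dwell
  enforcement merges runs shorter than `min_dwell_s` into their longer
  neighbour, shortest run first, ties merging backward in time — a
  deterministic tie-break.
- **Step-edge deduplication.** A level transition is a step in the raw trace
  and therefore leaks a transient of roughly the step size into the
  high-passed fast band. At the calibrated kinetics this would add several
  false "spikes" per minute — more than the true day-1 rate. These
  transients are the same physical events as the dwell edges, so detections
  centred within `class_boundary_s` (0.1 s) of a *candidate* step edge are
  removed. Candidate edges come from the debounced hard assignment before
  dwell enforcement (debounce: runs ≥ class_boundary_s / 2), so edges of
  dwells too short to be reported still guard against double counting. The
  cost is a ~2% blind fraction of the recording around edges, i.e. ~2% of
  true spikes.
- **Classification.** Remaining fast detections with duration ≥ 0.1 s are
  reclassified `rts_step` if centred inside a segmented dwell; otherwise
  they stay fast spikes (the 0.1 s boundary sits between the 50 ms maximum
  spike width and the 0.5 s dwell floor). The per-minute rate counts fast
  spikes by default (`rate_classes="all"` includes dwells); amplitude
  summaries pool both classes by default (`amp_classes="fast"` restricts).

## Summaries

Per-minute counts use tumbling (non-overlapping) 1-minute windows anchored at
t = 0, last partial window dropped. Quartiles are median, 25th/75th
percentiles with linear interpolation between order statistics, and maximum —
one convention, used everywhere, matched against a sort-based oracle in the
tests. The repletion contrast reports rate and amplitude median ratios of
each post-repletion day to starvation day 4 and two flags: `decline_24h`
(day-5 rate median strictly below day 4) and `near_baseline_48h` (day-6 rate
median within 1 event/min of day 1).

## What the simulator does and does not emulate

It reproduces the *statistical structure* the readout measures: two event
classes on their time scales, per-day rate and amplitude quartiles, 1/f
noise, drift. It does not emulate electrode/electrolyte physics (double-layer
capacitance, EPS impedance growth), biofilm architecture, light–dark
photosynthetic dynamics (recordings are dark-phase), spatial correlation
across electrodes, or any waveform detail beyond amplitude and width. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims on signals with this structure — not that real recordings have exactly
this structure.

## Known limitations and edge behaviour

- Telegraph dwells below `min_dwell_s` (≈ 22% of dwells at a 2 s mean) are
  below the detector's dwell floor by design; a sub-floor *low* gap fuses its
  neighbouring dwells. Recovery guarantees therefore apply to representable
  dwells — those whose own duration and flanking gaps reach the floor. Their
  edges are still deduplicated from the spike channel via candidate edges.
- Detected rates run slightly below truth when the amplitude law has
  substantial mass below the 5σ threshold (e.g. ~16% of day-5 events at the
  default noise floor), and the rate median rounds that loss to integer
  events/min. This is threshold censoring, not a bug; lowering `k_sigma`
  trades it against false positives.
- A spike landing within 0.1 s of a step edge is attributed to the edge and
  lost (~2% at default kinetics).
- Amplitudes of telegraph events all equal the fitted level separation; at
  high event counts the pooled amplitude median is pinned to it.
- Noise-free traces give σ = 0; the pipeline substitutes a tiny positive
  scale so that any rendered event is still detected.

## Problem sizes used by the test suite

Monte-Carlo tests state their own sizes; the main ones: dwell statistics
pool > 500 dwells per state (30 × 400 s at 200 Hz, plus 200 × 100 s for the
generator sanity check); Poisson dispersion uses 200 replicates of 600 s;
end-to-end recovery runs the six-condition schedule at full length (3600 s,
2 kHz) for one fixed seed, the repletion contrast 100 seeds at 600 s, the
telegraph-recovery check 50 seeds of 300 s at 500 Hz, and oracle-equivalence
checks 100 random traces of ≤ 10⁴ samples. Spike-detection F1 against ground
truth on the busiest day exceeds 0.9 (8 seeds × 600 s).
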