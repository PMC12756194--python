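"""Seeded synthetic voltage traces for the starvation/repletion day course.

The simulator renders the two event classes seen in extracellular recordings
of *Oscillatoria* sp. cohorts — millisecond high-amplitude spikes and
seconds-scale random-telegraph (RTS) two-state fluctuations — on a noise floor
of white + 1/f Gaussian noise with a slow drift ramp. The default six-condition
schedule (four days of nitrogen starvation, then two days after 5 mg/L NH4+
addition) is calibrated so that the true per-minute spike-rate median and the
amplitude quartiles of each day reproduce the published per-day summary
statistics (see :data:`DAY_SUMMARY`).

Determinism contract: every public generator takes a seed (or a
``numpy.random.SeedSequence``); :func:`synthesize_schedule` derives one
sub-seed per (condition index, component stream) via ``SeedSequence`` spawn
keys, so each condition trace is independently reproducible from the master
seed. Stream ids: 0 = spikes, 1 = telegraph, 2 = noise.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import fft as sp_fft
from scipy import stats

from .errors import ParameterError
from .types import (
    CONDITION_ORDER,
    FAST_SPIKE,
    RTS_STEP,
    Condition,
    ConditionSchedule,
    EventRecord,
    GroundTruth,
    NoiseParams,
    RtsParams,
    SpikeParams,
    TraceMeta,
    VoltageTrace,
)

#: Standard-normal quartile, ``scipy.stats.norm.ppf(0.75)``.
_Z75 = float(stats.norm.ppf(0.75))

#: Per-day calibration targets: for each condition, the per-minute spike-rate
#: quartiles ``freq = (q2, iqr_lo, iqr_hi, q4)`` and the event-amplitude
#: quartiles ``amp`` in µV, with Q4 read as the observed maximum.
DAY_SUMMARY = {
    "-Nd1":   {"day": 1, "freq": (1.0, 1.0, 6.0, 9.0),  "amp": (3.5, 2.6, 5.0, 8.5)},
    "-Nd2":   {"day": 2, "freq": (2.0, 1.0, 5.0, 11.0), "amp": (3.7, 2.7, 5.2, 9.0)},
    "-Nd3":   {"day": 3, "freq": (1.0, 1.0, 2.0, 3.0),  "amp": (6.0, 3.8, 9.2, 17.4)},
    "-Nd4":   {"day": 4, "freq": (5.0, 1.0, 32.0, 82.0), "amp": (6.0, 3.7, 9.4, 17.0)},
    "NH4+d1": {"day": 5, "freq": (3.0, 1.0, 8.0, 18.0), "amp": (3.6, 2.5, 5.2, 9.0)},
    "NH4+d2": {"day": 6, "freq": (1.0, 1.0, 2.0, 3.0),  "amp": (4.7, 3.0, 6.5, 12.0)},
}

#: Telegraph kinetics per day. The slow two-state activity strengthens with
#: starvation (days 3-4) and relaxes after repletion; the mean high-state dwell
#: is 1/k_down = 2 s throughout (the "seconds scale" of the slow class).
_RTS_KINETICS = {
    "-Nd1": (0.05, 0.5), "-Nd2": (0.05, 0.5), "-Nd3": (0.10, 0.5),
    "-Nd4": (0.10, 0.5), "NH4+d1": (0.05, 0.5), "NH4+d2": (0.03, 0.5),
}

#: Background defaults: ~0.3 µV white floor so 3-4 µV spikes clear a 5-sigma
#: threshold, a stronger 1/f component confined to the slow band, and a gentle
#: drift ramp.
DEFAULT_NOISE = NoiseParams(white_sd_uv=0.3, pink_sd_uv=0.5, drift_uv_per_min=0.5)

#: Default sampling rate (Hz): resolves 5-ms pulses with ten samples while
#: keeping an hour-long trace at 7.2 M samples.
DEFAULT_FS_HZ = 2000.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def calibrate_amplitude(q2: float, iqr_lo: float, iqr_hi: float, q4: float
                        ) -> tuple[float, float]:
    """Fit a log-normal amplitude law to published quartiles.

    The median is matched exactly (``amp_median_uv = q2``); the log-scale
    spread is the least-squares fit of the two inner quartiles on the log
    scale, which has the closed form ``ln(iqr_hi/iqr_lo) / (2 z_0.75)``.
    ``q4`` is the observed maximum of the published sample and is not a
    distribution parameter, so it is validated but not fitted.

    Returns ``(amp_median_uv, amp_spread)``.
    """
    if not (0 < iqr_lo < q2 < iqr_hi <= q4):
        raise ParameterError(
            "amplitude quartiles must satisfy 0 < iqr_lo < q2 < iqr_hi <= q4, "
            f"got {(iqr_lo, q2, iqr_hi, q4)}")
    spread = math.log(iqr_hi / iqr_lo) / (2.0 * _Z75)
    return float(q2), float(spread)


def generate_rts(duration_s: float, fs_hz: float, rts: RtsParams, seed
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-level telegraph signal with exponential dwell times.

    The process starts in the low state (level 0) and alternates with the
    high state (level ``step_uv``); dwell durations are exponential with rate
    ``k_up`` in the low state and ``k_down`` in the high state, quantized to
    at least one sample. A zero rate makes the corresponding state absorbing.

    Returns ``(contribution µV, per-sample state in {0, 1})``.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    n = int(round(duration_s * fs_hz))
    rng = _as_rng(seed)
    state = np.zeros(n, dtype=np.int8)

    pos = 0
    cur = 0  # 0 = low, 1 = high
    while pos < n:
        rate = rts.k_up if cur == 0 else rts.k_down
        if rate <= 0:
            # absorbing state: fill the remainder
            state[pos:] = cur
            break
        dwell_s = rng.exponential(1.0 / rate)
        dwell_n = max(1, int(round(dwell_s * fs_hz)))
        state[pos:pos + dwell_n] = cur
        pos += dwell_n
        cur = 1 - cur
    return state.astype(float) * rts.step_uv, state


def rts_events_from_state(state: np.ndarray, fs_hz: float, step_uv: float
                          ) -> list[EventRecord]:
    """One :data:`RTS_STEP` event per high-state dwell in a state sequence."""
    state = np.asarray(state)
    if state.size == 0:
        return []
    edges = np.flatnonzero(np.diff(state.astype(np.int8)) != 0) + 1
    bounds = np.concatenate([[0], edges, [state.size]])
    events = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if state[a]:
            events.append(EventRecord(onset_s=a / fs_hz, peak_amp_uv=float(step_uv),
                                      duration_s=(b - a) / fs_hz, event_class=RTS_STEP))
    return events


def generate_spikes(duration_s: float, fs_hz: float, spike: SpikeParams, seed
                    ) -> tuple[np.ndarray, list[EventRecord]]:
    """Render millisecond spikes: Poisson times, log-normal peak amplitudes.

    Each event is a smooth unimodal (Gaussian-bell) pulse whose full width is
    ``width_ms`` (taken as the ±3-sigma extent of the bell); overlapping
    pulses sum. The sign is positive with probability ``polarity_prob_pos``;
    ground-truth amplitudes are recorded unsigned since detection is
    polarity-agnostic.

    Returns ``(contribution µV, ground-truth event list sorted by onset)``.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    width_n = spike.width_ms * 1e-3 * fs_hz
    if width_n < 2:
        raise ParameterError(
            f"width_ms={spike.width_ms} spans {width_n:.2f} samples at fs={fs_hz} Hz; "
            "need >= 2 samples to separate the spike class")
    n = int(round(duration_s * fs_hz))
    rng = _as_rng(seed)
    out = np.zeros(n)

    n_events = rng.poisson(spike.rate_per_min / 60.0 * duration_s)
    if n_events == 0:
        return out, []
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    amps = spike.amp_median_uv * np.exp(spike.amp_spread * rng.standard_normal(n_events))
    signs = np.where(rng.uniform(size=n_events) < spike.polarity_prob_pos, 1.0, -1.0)

    sigma_t = spike.width_ms * 1e-3 / 6.0  # full width = ±3 sigma
    half = max(1, int(round(3 * sigma_t * fs_hz)))
    kernel_t = (np.arange(-half, half + 1) / fs_hz)
    kernel = np.exp(-0.5 * (kernel_t / sigma_t) ** 2)

    events = []
    for t0, amp, sign in zip(times, amps, signs):
        c = int(round(t0 * fs_hz))
        a = max(0, c - half)
        b = min(n, c + half + 1)
        out[a:b] += sign * amp * kernel[a - (c - half): b - (c - half)]
        events.append(EventRecord(onset_s=float(t0), peak_amp_uv=float(amp),
                                  duration_s=spike.width_ms * 1e-3,
                                  event_class=FAST_SPIKE))
    return out, events


def generate_noise(duration_s: float, fs_hz: float, noise: NoiseParams, seed
                   ) -> np.ndarray:
    """White + 1/f Gaussian noise plus a deterministic drift ramp, in µV.

    The pink component is white noise shaped in the frequency domain by
    ``1/sqrt(f)`` (zero DC) and rescaled to the requested standard deviation,
    giving a power spectrum with slope ≈ −1 on log-log axes.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    n = int(round(duration_s * fs_hz))
    rng = _as_rng(seed)
    out = np.zeros(n)

    if noise.white_sd_uv > 0:
        out += noise.white_sd_uv * rng.standard_normal(n)
    if noise.pink_sd_uv > 0 and n > 1:
        w = rng.standard_normal(n)
        spec = sp_fft.rfft(w)
        f = sp_fft.rfftfreq(n, d=1.0 / fs_hz)
        shape = np.zeros_like(f)
        shape[1:] = 1.0 / np.sqrt(f[1:])
        pink = sp_fft.irfft(spec * shape, n=n)
        sd = pink.std()
        if sd > 0:
            out += noise.pink_sd_uv / sd * pink
    if noise.drift_uv_per_min != 0:
        out += noise.drift_uv_per_min / 60.0 * (np.arange(n) / fs_hz)
    return out


def _condition_from_summary(label: str, duration_s: float) -> Condition:
    row = DAY_SUMMARY[label]
    amp_median, amp_spread = calibrate_amplitude(*row["amp"])
    k_up, k_down = _RTS_KINETICS[label]
    return Condition(
        label=label,
        spike=SpikeParams(rate_per_min=row["freq"][0], amp_median_uv=amp_median,
                          amp_spread=amp_spread),
        # step level = that day's amplitude median, so the pooled (spike +
        # telegraph) amplitude distribution keeps its median on target
        rts=RtsParams(k_up=k_up, k_down=k_down, step_uv=row["amp"][0]),
        noise=DEFAULT_NOISE,
        duration_s=duration_s,
    )


def default_schedule(duration_s: float = 3600.0) -> ConditionSchedule:
    """The six-condition day course calibrated to the published summary table."""
    return ConditionSchedule(tuple(
        _condition_from_summary(label, duration_s) for label in CONDITION_ORDER))


def synthesize_condition(cond: Condition, fs_hz: float, seed_seqs
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Render spikes + telegraph + noise for one condition (additive, exact)."""
    spike_seed, rts_seed, noise_seed = seed_seqs
    spikes, spike_events = generate_spikes(cond.duration_s, fs_hz, cond.spike, spike_seed)
    rts_sig, state = generate_rts(cond.duration_s, fs_hz, cond.rts, rts_seed)
    noise = generate_noise(cond.duration_s, fs_hz, cond.noise, noise_seed)
    samples = spikes + rts_sig + noise
    events = sorted(spike_events + rts_events_from_state(state, fs_hz, cond.rts.step_uv),
                    key=lambda e: e.onset_s)
    return samples, GroundTruth(events=events, rts_state=state)


def synthesize_schedule(schedule: ConditionSchedule, fs_hz: float = DEFAULT_FS_HZ,
                        seed: int = 0) -> list[tuple[VoltageTrace, GroundTruth]]:
    """Generate one annotated trace per condition of *schedule*.

    Sub-seeds are ``SeedSequence(seed, spawn_key=(i, stream))`` for condition
    index ``i`` and stream 0/1/2 (spikes/telegraph/noise): fixed, documented,
    and independent of which other conditions are generated.
    """
    out = []
    for i, cond in enumerate(schedule):
        seqs = [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, s)))
                for s in range(3)]
        samples, truth = synthesize_condition(cond, fs_hz, seqs)
        day = DAY_SUMMARY[cond.label]["day"] if cond.label in DAY_SUMMARY else i + 1
        meta = TraceMeta(fs_hz=fs_hz, condition=cond.label, day_index=day, seed=seed)
        out.append((VoltageTrace(fs_hz=fs_hz, samples=samples, meta=meta), truth))
    return out
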