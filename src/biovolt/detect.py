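"""Event detection: fast-spike thresholding and telegraph-state segmentation.

Spikes are threshold crossings of the fast band at ``k_sigma`` times the
robust (MAD-based) noise scale, polarity-agnostic, with nearby supra-threshold
excursions merged within a refractory window. The slow band is idealized into
a two-level telegraph process by a two-component equal-variance Gaussian
mixture on sample values, hard assignment at the level midpoint, and a
minimum-dwell constraint that removes assignment chatter.

A physical subtlety ties the two detectors together: every telegraph level
transition leaks a step-edge transient of roughly the step size into the
high-passed fast band. Those transients are the *same* physical events as the
segmented dwell edges, so :func:`merge_and_classify` removes fast-band
detections centred within ``class_boundary_s`` of a candidate step edge
rather than double-counting them as spikes (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import ParameterError
from .preprocess import MAD_TO_SD
from .types import (
    FAST_SPIKE,
    RTS_STEP,
    DetectionConfig,
    EventRecord,
    check_sorted,
)

#: Decimated rate (Hz) at which telegraph segmentation operates; dwell
#: constraints are >= 0.5 s, so 200 Hz keeps boundary quantization error
#: below 0.5% of the shortest admissible dwell.
_SEG_MAX_HZ = 200.0

#: Largest sample count handed to the mixture fit (strided subsample).
_GMM_MAX_SAMPLES = 50_000


def _runs(mask_or_state: np.ndarray) -> list[list[int]]:
    """Contiguous runs as ``[start, stop, value]`` triples (stop exclusive)."""
    x = np.asarray(mask_or_state)
    if x.size == 0:
        return []
    edges = np.flatnonzero(np.diff(x) != 0) + 1
    bounds = np.concatenate([[0], edges, [x.size]])
    return [[int(a), int(b), int(x[a])] for a, b in zip(bounds[:-1], bounds[1:])]


def detect_spikes(fast: np.ndarray, fs_hz: float, sigma: float,
                  config: DetectionConfig | None = None) -> list[EventRecord]:
    """Threshold the fast band at ±k_sigma·sigma and emit one event per excursion.

    Contiguous supra-threshold excursions separated by no more than
    ``refractory_ms`` are merged into one event whose amplitude is the maximum
    absolute excursion and whose duration is the supra-threshold extent.
    Events come back sorted by onset. An empty trace yields an empty list.
    """
    config = config or DetectionConfig()
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    fast = np.asarray(fast, dtype=float)
    if fast.size == 0:
        return []
    if not np.all(np.isfinite(fast)):
        raise ParameterError("trace contains non-finite samples")

    thr = config.k_sigma * sigma
    mask = np.abs(fast) >= thr
    runs = [r for r in _runs(mask) if r[2]]
    if not runs:
        return []

    refractory_n = int(round(config.refractory_ms * 1e-3 * fs_hz))
    merged = [runs[0][:2]]
    for a, b, _ in runs[1:]:
        if a - merged[-1][1] <= refractory_n:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        seg = fast[a:b]
        events.append(EventRecord(
            onset_s=a / fs_hz,
            peak_amp_uv=float(np.max(np.abs(seg))),
            duration_s=(b - a) / fs_hz,
            event_class=FAST_SPIKE,
        ))
    return events


@dataclass
class RtsSegmentation:
    """Result of two-state idealization of the slow band.

    ``no_rts`` is set (with empty events and an all-zero state) when the
    fitted level separation is indistinguishable from the residual noise —
    a flat trace is an answer, not an error. ``transition_times_s`` are the
    candidate step edges of the debounced hard assignment *before* the
    minimum-dwell constraint; they drive step-edge deduplication in
    :func:`merge_and_classify` and include edges of dwells too short to be
    reported as events.
    """

    state: np.ndarray
    events: list[EventRecord]
    no_rts: bool
    level_low: float = 0.0
    level_high: float = 0.0
    residual_sigma: float = 0.0
    transition_times_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def separation_uv(self) -> float:
        return self.level_high - self.level_low


def _merge_short_runs(runs: list[list[int]], min_len: int) -> list[list[int]]:
    """Absorb runs shorter than *min_len* into their longer neighbour.

    The shortest run is processed first (earlier run on a length tie); on a
    neighbour-length tie it merges backward in time. States alternate, so an
    absorbed run fuses with both neighbours.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [b - a for a, b, _ in runs]
        idx = int(np.argmin(lengths))
        if lengths[idx] >= min_len:
            break
        prev_len = lengths[idx - 1] if idx > 0 else -1
        next_len = lengths[idx + 1] if idx < len(runs) - 1 else -1
        into_prev = prev_len >= next_len  # backward on tie
        if into_prev:
            runs[idx - 1][1] = runs[idx][1]
            del runs[idx]
            if idx < len(runs) and runs[idx - 1][2] == runs[idx][2]:
                runs[idx - 1][1] = runs[idx][1]
                del runs[idx]
        else:
            runs[idx + 1][0] = runs[idx][0]
            del runs[idx]
            if idx > 0 and runs[idx - 1][2] == runs[idx][2]:
                runs[idx - 1][1] = runs[idx][1]
                del runs[idx]
    return runs


def _runs_to_state(runs: list[list[int]], n: int) -> np.ndarray:
    state = np.zeros(n, dtype=np.int8)
    for a, b, v in runs:
        state[a:b] = v
    return state


def segment_rts(slow: np.ndarray, fs_hz: float,
                config: DetectionConfig | None = None) -> RtsSegmentation:
    """Idealize the slow band into a two-level telegraph state sequence.

    Level estimates come from a two-component tied-covariance Gaussian
    mixture (means initialized at the 25th/99th percentiles, fixed random
    state); samples are hard-assigned at the level midpoint; runs shorter
    than ``min_dwell_s`` are merged into their longer neighbour. One
    :data:`RTS_STEP` event is emitted per surviving high dwell with amplitude
    equal to the fitted level separation.
    """
    config = config or DetectionConfig()
    slow = np.asarray(slow, dtype=float)
    n = slow.size
    if n / fs_hz < 10 * config.min_dwell_s:
        raise ParameterError(
            f"trace of {n / fs_hz:.1f} s is shorter than 10 x min_dwell_s "
            f"({config.min_dwell_s} s)")

    step = max(1, int(fs_hz // _SEG_MAX_HZ))
    z = slow[::step]
    fs_d = fs_hz / step

    flat = RtsSegmentation(state=np.zeros(n, dtype=np.int8), events=[], no_rts=True)
    if np.ptp(z) == 0:
        return flat

    zfit = z[:: max(1, int(np.ceil(z.size / _GMM_MAX_SAMPLES)))].reshape(-1, 1)
    means_init = np.percentile(zfit, [25.0, 99.0]).reshape(-1, 1)
    if means_init[0, 0] == means_init[1, 0]:
        return flat
    gmm = GaussianMixture(n_components=2, covariance_type="tied",
                          means_init=means_init, random_state=0, max_iter=200)
    gmm.fit(zfit)
    mu_lo, mu_hi = np.sort(gmm.means_.ravel())
    sep = float(mu_hi - mu_lo)
    residual_sigma = float(np.sqrt(gmm.covariances_.ravel()[0]))

    # degenerate unless the data genuinely support two levels: the two-level
    # model must beat a single Gaussian (BIC) and the levels must sit at
    # least two within-level sigmas apart (bimodality threshold)
    one = GaussianMixture(n_components=1, random_state=0).fit(zfit)
    if one.bic(zfit) <= gmm.bic(zfit) or sep < 2 * residual_sigma:
        flat.residual_sigma = residual_sigma
        return flat

    assign = (z > (mu_lo + mu_hi) / 2).astype(np.int8)

    # debounce: chatter shorter than half the class boundary cannot be a dwell
    # but its edges are still candidate step transients
    debounce_n = max(2, int(round(config.class_boundary_s / 2 * fs_d)))
    runs = _merge_short_runs(_runs(assign), debounce_n)
    candidate_edges = np.array([r[0] for r in runs[1:]], dtype=float) * step / fs_hz

    min_dwell_n = max(1, int(round(config.min_dwell_s * fs_d)))
    runs = _merge_short_runs(runs, min_dwell_n)
    state_d = _runs_to_state(runs, z.size)
    state = np.repeat(state_d, step)[:n]
    if state.size < n:  # fs not an integer multiple of the decimation step
        state = np.pad(state, (0, n - state.size), mode="edge")

    events = []
    for a, b, v in _runs(state):
        if v:
            events.append(EventRecord(onset_s=a / fs_hz, peak_amp_uv=sep,
                                      duration_s=(b - a) / fs_hz,
                                      event_class=RTS_STEP))
    return RtsSegmentation(state=state, events=events, no_rts=False,
                           level_low=float(mu_lo), level_high=float(mu_hi),
                           residual_sigma=residual_sigma,
                           transition_times_s=candidate_edges)


def merge_and_classify(spike_events: list[EventRecord],
                       rts_events: list[EventRecord],
                       config: DetectionConfig | None = None,
                       transition_times_s: np.ndarray | None = None
                       ) -> list[EventRecord]:
    """Combine the two detector outputs into one chronological event list.

    Fast-band detections centred within ``class_boundary_s`` of a candidate
    step edge are the edge transients of the telegraph transitions already
    represented by dwell events, and are removed. A remaining fast detection
    whose duration reaches ``class_boundary_s`` is reclassified ``rts_step``
    only if its centre falls inside a segmented high dwell; otherwise it stays
    a fast spike. Dwell events pass through unchanged.
    """
    config = config or DetectionConfig()
    check_sorted(spike_events, "spike events")
    check_sorted(rts_events, "rts events")

    if transition_times_s is None:
        edges = []
        for e in rts_events:
            edges.extend((e.onset_s, e.onset_s + e.duration_s))
        transition_times_s = np.asarray(sorted(edges))
    else:
        transition_times_s = np.asarray(transition_times_s, dtype=float)

    dwells = [(e.onset_s, e.onset_s + e.duration_s) for e in rts_events]

    kept = []
    for e in spike_events:
        center = e.onset_s + e.duration_s / 2
        if transition_times_s.size:
            i = np.searchsorted(transition_times_s, center)
            near = min(
                abs(center - transition_times_s[max(0, i - 1)]),
                abs(center - transition_times_s[min(i, transition_times_s.size - 1)]),
            )
            if near < config.class_boundary_s:
                continue  # step-edge transient, already counted as a dwell
        if e.duration_s >= config.class_boundary_s and any(
                a <= center <= b for a, b in dwells):
            e = EventRecord(onset_s=e.onset_s, peak_amp_uv=e.peak_amp_uv,
                            duration_s=e.duration_s, event_class=RTS_STEP)
        kept.append(e)

    out = kept + list(rts_events)
    out.sort(key=lambda e: (e.onset_s, e.event_class))
    return out
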