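"""Core value types shared across the simulator, the detector and the I/O layer.

All voltages are in microvolts (µV), all times in seconds unless a field name
says otherwise (``width_ms``, ``refractory_ms``). Parameter containers validate
eagerly on construction and raise :class:`~biovolt.errors.ParameterError`
naming the offending field, so a bad configuration fails before any signal is
generated or analysed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError

#: Event class label for millisecond-scale transient spikes.
FAST_SPIKE = "fast_spike"
#: Event class label for seconds-scale random-telegraph (two-state) dwells.
RTS_STEP = "rts_step"

#: The six conditions of the starvation/repletion day course, in design order:
#: four days of nitrogen starvation followed by two days after ammonium
#: addition (5 mg/L NH4+).
CONDITION_ORDER = ("-Nd1", "-Nd2", "-Nd3", "-Nd4", "NH4+d1", "NH4+d2")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(x: float, name: str) -> None:
    _require(math.isfinite(x), f"{name} must be finite, got {x!r}")


@dataclass(frozen=True)
class SpikeParams:
    """Millisecond spike process: Poisson times, log-normal amplitudes.

    Parameters
    ----------
    rate_per_min : float
        Homogeneous Poisson event rate, events per minute, >= 0.
    amp_median_uv : float
        Median of the log-normal peak-amplitude law, µV, > 0.
    amp_spread : float
        Log-scale standard deviation of the amplitude law, >= 0.
    width_ms : float
        Full width of the rendered pulse in milliseconds, in (0.5, 50).
    polarity_prob_pos : float
        Probability that an event deflects positive; detection is
        polarity-agnostic, so this only shapes the raw trace.
    """

    rate_per_min: float
    amp_median_uv: float
    amp_spread: float
    width_ms: float = 5.0
    polarity_prob_pos: float = 0.5

    def __post_init__(self) -> None:
        _finite(self.rate_per_min, "rate_per_min")
        _require(self.rate_per_min >= 0, f"rate_per_min must be >= 0, got {self.rate_per_min}")
        _require(self.amp_median_uv > 0, f"amp_median_uv must be > 0, got {self.amp_median_uv}")
        _require(self.amp_spread >= 0, f"amp_spread must be >= 0, got {self.amp_spread}")
        _require(0.5 < self.width_ms < 50, f"width_ms must be in (0.5, 50) ms, got {self.width_ms}")
        _require(0 <= self.polarity_prob_pos <= 1,
                 f"polarity_prob_pos must be in [0, 1], got {self.polarity_prob_pos}")


@dataclass(frozen=True)
class RtsParams:
    """Two-state random telegraph process with exponential dwell times.

    ``k_up`` is the low-to-high transition rate (1/s), ``k_down`` the
    high-to-low rate; the mean dwell in the high state is ``1/k_down``.
    ``step_uv`` is the level separation between the two states.
    """

    k_up: float
    k_down: float
    step_uv: float

    def __post_init__(self) -> None:
        _finite(self.k_up, "k_up")
        _finite(self.k_down, "k_down")
        _require(self.k_up >= 0, f"k_up must be >= 0, got {self.k_up}")
        _require(self.k_down >= 0, f"k_down must be >= 0, got {self.k_down}")
        _require(self.step_uv > 0, f"step_uv must be > 0, got {self.step_uv}")


@dataclass(frozen=True)
class NoiseParams:
    """Background model: white + 1/f (pink) Gaussian noise and a linear drift.

    With all three fields zero the generated noise is identically zero.
    """

    white_sd_uv: float = 0.0
    pink_sd_uv: float = 0.0
    drift_uv_per_min: float = 0.0

    def __post_init__(self) -> None:
        _require(self.white_sd_uv >= 0, f"white_sd_uv must be >= 0, got {self.white_sd_uv}")
        _require(self.pink_sd_uv >= 0, f"pink_sd_uv must be >= 0, got {self.pink_sd_uv}")
        _finite(self.drift_uv_per_min, "drift_uv_per_min")


@dataclass(frozen=True)
class Condition:
    """One recording day: label plus the three generator parameter blocks."""

    label: str
    spike: SpikeParams
    rts: RtsParams
    noise: NoiseParams
    duration_s: float

    def __post_init__(self) -> None:
        _require(self.duration_s > 0, f"duration_s must be > 0, got {self.duration_s}")


@dataclass(frozen=True)
class ConditionSchedule:
    """Ordered starvation/repletion design; labels must be unique."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        _require(len(labels) == len(set(labels)),
                 f"duplicate condition labels in schedule: {labels}")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def __iter__(self):
        return iter(self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)


@dataclass(frozen=True)
class TraceMeta:
    """Sidecar metadata for a trace; units are fixed to microvolts."""

    fs_hz: float
    condition: str
    day_index: int
    seed: int | None = None
    units: str = "uV"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.fs_hz > 0, f"fs_hz must be > 0, got {self.fs_hz}")
        _require(self.day_index >= 1, f"day_index must be >= 1, got {self.day_index}")


@dataclass
class VoltageTrace:
    """Uniformly sampled single-channel voltage series, in µV."""

    fs_hz: float
    samples: np.ndarray
    meta: TraceMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        _require(self.fs_hz > 0, f"fs_hz must be > 0, got {self.fs_hz}")
        _require(self.samples.ndim == 1, "samples must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class EventRecord:
    """One detected or ground-truth event.

    ``peak_amp_uv`` is the absolute, baseline-subtracted peak amplitude; for a
    telegraph dwell it is the fitted level separation.
    """

    onset_s: float
    peak_amp_uv: float
    duration_s: float
    event_class: str

    def __post_init__(self) -> None:
        _require(self.duration_s > 0, f"duration_s must be > 0, got {self.duration_s}")
        _require(self.event_class in (FAST_SPIKE, RTS_STEP),
                 f"event_class must be one of {(FAST_SPIKE, RTS_STEP)}, got {self.event_class!r}")


@dataclass
class GroundTruth:
    """Simulator annotations: true events plus the per-sample telegraph state."""

    events: list[EventRecord]
    rts_state: np.ndarray

    def __post_init__(self) -> None:
        self.rts_state = np.asarray(self.rts_state, dtype=np.int8)


@dataclass(frozen=True)
class DetectionConfig:
    """All thresholds and time constants of the analysis, one reproducible block.

    ``k_sigma`` multiplies the robust (MAD-based) noise scale of the fast band
    to form the spike threshold; 5 is the conservative convention for
    extracellular recordings. ``class_boundary_s`` separates the millisecond
    spike class from the seconds-scale telegraph class and must stay below
    ``min_dwell_s``.
    """

    k_sigma: float = 5.0
    refractory_ms: float = 20.0
    class_boundary_s: float = 0.1
    min_dwell_s: float = 0.5
    fc_hz: float = 10.0
    baseline_window_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("k_sigma", "refractory_ms", "class_boundary_s",
                     "min_dwell_s", "fc_hz", "baseline_window_s"):
            _require(getattr(self, name) > 0, f"{name} must be > 0, got {getattr(self, name)}")
        _require(self.class_boundary_s < self.min_dwell_s,
                 "class_boundary_s must be < min_dwell_s "
                 f"({self.class_boundary_s} >= {self.min_dwell_s})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        _require(not unknown, f"unknown DetectionConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class BandSplit:
    """Fast/slow decomposition of a detrended trace.

    ``fast + slow + baseline`` reconstructs the raw input exactly by
    construction (the slow band is the complement of the zero-phase high-pass).
    """

    fast: np.ndarray
    slow: np.ndarray
    fc_hz: float
    baseline: np.ndarray


@dataclass(frozen=True)
class QuartileSummary:
    """One summary row per condition: Q2 / IQR bounds / observed maximum (Q4)
    for the per-minute event rate and for the pooled event amplitudes."""

    condition: str
    freq_q2: float
    freq_iqr_lo: float
    freq_iqr_hi: float
    freq_q4: float
    amp_q2: float
    amp_iqr_lo: float
    amp_iqr_hi: float
    amp_q4: float
    amp_empty: bool = False

    def __post_init__(self) -> None:
        for prefix in ("freq", "amp"):
            lo = getattr(self, f"{prefix}_iqr_lo")
            q2 = getattr(self, f"{prefix}_q2")
            hi = getattr(self, f"{prefix}_iqr_hi")
            q4 = getattr(self, f"{prefix}_q4")
            _require(lo <= q2 <= hi <= q4,
                     f"{prefix} quartiles must satisfy lo <= q2 <= hi <= q4, "
                     f"got {(lo, q2, hi, q4)}")


def check_sorted(events: Sequence[EventRecord], what: str = "events") -> None:
    """Raise if *events* are not sorted by onset (shared pre-condition)."""
    from .errors import UnsortedEventsError

    onsets = [e.onset_s for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise UnsortedEventsError(f"{what} must be sorted by onset_s")
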