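"""Baseline removal, fast/slow band separation and robust noise estimation.

The two event classes live on well-separated time scales (milliseconds vs
seconds), so the analysis splits each detrended trace at a corner frequency
``fc_hz`` (default 10 Hz, two octaves away from each class): the zero-phase
high-pass output is the *fast* band used for spike detection; its complement
is the *slow* band used for telegraph segmentation. Zero-phase
(forward-backward) filtering keeps event peak times and amplitudes unbiased,
and defining the slow band as ``detrended - fast`` makes the decomposition
``fast + slow + baseline == raw`` exact sample-wise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ParameterError
from .types import BandSplit, DetectionConfig, VoltageTrace

#: Consistency factor turning a median absolute deviation into a Gaussian s.d.
MAD_TO_SD = 1.4826

#: Target rate (Hz) at which the running-median baseline is evaluated before
#: being interpolated back to the full sampling grid. The baseline varies on
#: the minutes scale, so 20 Hz oversamples it by orders of magnitude while
#: keeping the rolling median affordable on hour-long traces.
_BASELINE_EVAL_HZ = 20.0


def remove_baseline(samples: np.ndarray, fs_hz: float, window_s: float = 60.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a running-median baseline; returns ``(detrended, baseline)``.

    The window should be at least ~10x the telegraph dwell scale so the
    two-state steps are not absorbed into the baseline. The median is
    evaluated on a decimated grid (robust to spikes by construction) and
    linearly interpolated back; the residual is recentered to zero median.
    """
    samples = np.asarray(samples, dtype=float)
    win_n = int(round(window_s * fs_hz))
    if win_n < 3:
        raise ParameterError(
            f"baseline window of {window_s} s spans {win_n} samples at "
            f"fs={fs_hz} Hz; need >= 3")
    n = samples.size
    step = max(1, int(fs_hz // _BASELINE_EVAL_HZ))
    coarse = samples[::step]
    # even window: the median interpolates between the two central order
    # statistics, which keeps the baseline stable between the levels of a
    # two-state signal even at 50% duty
    win_c = max(4, int(round(win_n / step)) & ~1)
    base_c = (pd.Series(coarse)
              .rolling(win_c, center=True, min_periods=1)
              .median()
              .to_numpy())
    if step == 1:
        baseline = base_c
    else:
        baseline = np.interp(np.arange(n), np.arange(coarse.size) * step, base_c)
    detrended = samples - baseline
    shift = np.median(detrended)
    return detrended - shift, baseline + shift


def split_bands(samples: np.ndarray, fs_hz: float, fc_hz: float = 10.0,
                baseline: np.ndarray | None = None) -> BandSplit:
    """Zero-phase high-pass at ``fc_hz`` -> fast band; complement -> slow band.

    ``samples`` is expected to be already detrended; pass the removed
    ``baseline`` to carry it in the returned :class:`~biovolt.types.BandSplit`.
    """
    samples = np.asarray(samples, dtype=float)
    if not (0 < fc_hz < fs_hz / 2):
        raise ParameterError(
            f"fc_hz must lie in (0, fs/2) = (0, {fs_hz / 2}), got {fc_hz}")
    if samples.size == 0:
        empty = samples.copy()
        return BandSplit(fast=empty, slow=empty.copy(), fc_hz=fc_hz,
                         baseline=np.zeros(0) if baseline is None else baseline)
    sos = signal.butter(4, fc_hz, btype="highpass", fs=fs_hz, output="sos")
    fast = signal.sosfiltfilt(sos, samples)
    slow = samples - fast
    if baseline is None:
        baseline = np.zeros_like(samples)
    return BandSplit(fast=fast, slow=slow, fc_hz=fc_hz, baseline=baseline)


def preprocess_trace(trace: VoltageTrace, config: DetectionConfig | None = None
                     ) -> BandSplit:
    """Full preprocessing: running-median detrend, then band separation."""
    config = config or DetectionConfig()
    detrended, baseline = remove_baseline(trace.samples, trace.fs_hz,
                                          config.baseline_window_s)
    return split_bands(detrended, trace.fs_hz, config.fc_hz, baseline=baseline)


def noise_sigma(fast: np.ndarray, min_samples: int = 1000) -> float:
    """Robust noise scale of the fast band: 1.4826 x MAD about the median.

    Insensitive to constant offsets and to a small fraction of large spikes,
    which is exactly what the spike threshold needs.
    """
    fast = np.asarray(fast, dtype=float)
    if fast.size < min_samples:
        raise ParameterError(
            f"noise_sigma needs >= {min_samples} samples, got {fast.size}")
    med = np.median(fast)
    return float(MAD_TO_SD * np.median(np.abs(fast - med)))
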