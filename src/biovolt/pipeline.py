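"""End-to-end orchestration: simulate or load traces, detect, summarize, write.

``analyze_trace`` is the single-trace analysis used everywhere (tests, CLI,
acceptance): preprocess → robust noise scale → spike detection on the fast
band → telegraph segmentation on the slow band → merge/classify. ``run``
executes a full :class:`RunConfig` and writes every artifact plus a manifest
(config, seed, package version, SHA-256 of each output) sufficient to
reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .detect import RtsSegmentation, detect_spikes, merge_and_classify, segment_rts
from .errors import BiovoltError, ConfigError
from .io import read_trace, write_events, write_summary, write_trace
from .preprocess import noise_sigma, preprocess_trace
from .simulate import DEFAULT_FS_HZ, default_schedule, synthesize_schedule
from .summarize import (
    build_summary_table,
    events_per_minute,
    quartile_summary,
    repletion_response,
)
from .types import (
    FAST_SPIKE,
    ConditionSchedule,
    DetectionConfig,
    EventRecord,
    VoltageTrace,
)

log = logging.getLogger("biovolt")

#: CLI/pipeline exit codes: configuration errors vs I/O errors are distinct;
#: an empty detection is a warning, not a failure.
EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_IO = 3


@dataclass
class TraceAnalysis:
    """Everything the pipeline derives from one trace."""

    events: list[EventRecord]
    spike_events: list[EventRecord]
    rts: RtsSegmentation
    sigma_uv: float
    per_minute: np.ndarray
    condition: str


@dataclass
class RunConfig:
    """One reproducible run: either simulate a schedule or analyze trace files."""

    mode: str = "simulate"
    schedule: ConditionSchedule | None = None
    trace_paths: tuple = ()
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    fs_hz: float = DEFAULT_FS_HZ
    seed: int = 0
    out_dir: str = "biovolt_out"
    rate_classes: str = "fast"   # which classes enter the per-minute rate
    amp_classes: str = "all"     # which classes enter the amplitude pool
    write_traces: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if self.rate_classes not in ("fast", "all"):
            raise ConfigError(f"rate_classes must be 'fast' or 'all', got {self.rate_classes!r}")
        if self.amp_classes not in ("fast", "all"):
            raise ConfigError(f"amp_classes must be 'fast' or 'all', got {self.amp_classes!r}")
        if self.mode == "simulate" and self.schedule is None:
            self.schedule = default_schedule()
        if self.mode == "analyze" and not self.trace_paths:
            raise ConfigError("analyze mode requires at least one trace path")


def analyze_trace(trace: VoltageTrace, config: DetectionConfig | None = None
                  ) -> TraceAnalysis:
    """Run the full single-trace analysis chain."""
    config = config or DetectionConfig()
    band = preprocess_trace(trace, config)
    sigma = noise_sigma(band.fast)
    if sigma == 0:  # noise-free synthetic input: any excursion is real
        sigma = 1e-12
    spikes = detect_spikes(band.fast, trace.fs_hz, sigma, config)
    rts = segment_rts(band.slow, trace.fs_hz, config)
    events = merge_and_classify(spikes, rts.events, config,
                                transition_times_s=(None if rts.no_rts
                                                    else rts.transition_times_s))
    fast_only = [e for e in events if e.event_class == FAST_SPIKE]
    per_minute = events_per_minute(fast_only, trace.duration_s)
    return TraceAnalysis(events=events, spike_events=fast_only, rts=rts,
                         sigma_uv=sigma, per_minute=per_minute,
                         condition=trace.meta.condition)


def summarize_analysis(analysis: TraceAnalysis, rate_classes: str = "fast",
                       amp_classes: str = "all"):
    """Turn one trace analysis into a summary-table row."""
    if rate_classes == "fast":
        counts = analysis.per_minute
    else:  # recount over the merged list, same tumbling windows
        counts = events_per_minute(analysis.events,
                                   60.0 * len(analysis.per_minute))
    pool = (analysis.events if amp_classes == "all" else analysis.spike_events)
    amps = [e.peak_amp_uv for e in pool]
    return quartile_summary(counts, amps, analysis.condition)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> int:
    """Execute a run; returns a process exit code (0 on success)."""
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        log.error("cannot create output directory %s: %s", out, exc)
        return EXIT_IO

    try:
        if config.mode == "simulate":
            log.info("simulating %d conditions at fs=%g Hz, seed=%d",
                     len(config.schedule), config.fs_hz, config.seed)
            pairs = synthesize_schedule(config.schedule, config.fs_hz, config.seed)
            traces = [t for t, _ in pairs]
        else:
            traces = [read_trace(p) for p in config.trace_paths]
    except BiovoltError as exc:
        log.error("configuration/input error: %s", exc)
        return EXIT_CONFIG

    artifacts: list[Path] = []
    summaries = []
    empty_detection = False
    try:
        if config.mode == "simulate" and config.write_traces:
            for trace in traces:
                p = write_trace(out / f"trace_{_slug(trace.meta.condition)}.csv", trace)
                artifacts += [p, p.with_name(p.stem + ".meta.json")]

        for trace in traces:
            log.info("analyzing condition %s (%.0f s at %g Hz)",
                     trace.meta.condition, trace.duration_s, trace.fs_hz)
            analysis = analyze_trace(trace, config.detection)
            if not analysis.events:
                empty_detection = True
                log.warning("no events detected in condition %s", trace.meta.condition)
            if analysis.rts.no_rts:
                log.info("no RTS detected in condition %s", trace.meta.condition)
            p = write_events(out / f"events_{_slug(trace.meta.condition)}.csv",
                             analysis.events)
            artifacts.append(p)
            summaries.append(summarize_analysis(analysis, config.rate_classes,
                                                config.amp_classes))

        table = build_summary_table(summaries)
        p = write_summary(out / "summary.csv", table)
        artifacts.append(p)

        required = {"-Nd1", "-Nd4", "NH4+d1", "NH4+d2"}
        if required <= set(table["condition"]):
            contrast = repletion_response(table)
            p = out / "repletion_response.json"
            p.write_text(json.dumps(contrast, indent=1) + "\n", encoding="utf-8")
            artifacts.append(p)
            log.info("repletion contrast: decline_24h=%s near_baseline_48h=%s",
                     contrast["decline_24h"], contrast["near_baseline_48h"])
    except BiovoltError as exc:
        log.error("run failed: %s", exc)
        return EXIT_CONFIG
    except OSError as exc:
        log.error("I/O failure: %s", exc)
        return EXIT_IO

    manifest = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "fs_hz": config.fs_hz,
        "rate_classes": config.rate_classes,
        "amp_classes": config.amp_classes,
        "detection": config.detection.to_dict(),
        "schedule": (schedule_to_dict(config.schedule)
                     if config.schedule is not None else None),
        "trace_paths": [str(p) for p in config.trace_paths],
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n",
                                       encoding="utf-8")
    if empty_detection:
        log.warning("one or more conditions yielded no events")
    return EXIT_OK


def _slug(label: str) -> str:
    return label.replace("+", "p").replace("-", "m")


def schedule_to_dict(schedule: ConditionSchedule) -> dict:
    return {"conditions": [dataclasses.asdict(c) for c in schedule]}


def schedule_from_dict(d: dict) -> ConditionSchedule:
    from .types import Condition, NoiseParams, RtsParams, SpikeParams

    conds = []
    for c in d["conditions"]:
        conds.append(Condition(
            label=c["label"],
            spike=SpikeParams(**c["spike"]),
            rts=RtsParams(**c["rts"]),
            noise=NoiseParams(**c.get("noise", {})),
            duration_s=c["duration_s"],
        ))
    return ConditionSchedule(tuple(conds))
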