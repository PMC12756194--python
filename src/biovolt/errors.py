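"""Exception hierarchy.

Each failure mode the readers/writers and the pipeline can hit has a distinct
class so callers (and the CLI exit-code mapping) can discriminate without
string matching.
"""


class BiovoltError(Exception):
    """Base class for all package errors."""


class ParameterError(BiovoltError, ValueError):
    """A generator or detection parameter violates its contract."""


class MissingSidecarError(BiovoltError, FileNotFoundError):
    """A trace CSV has no metadata sidecar next to it."""


class NonUniformSamplingError(BiovoltError, ValueError):
    """The time column of a trace file is not uniformly sampled at fs_hz."""


class UnitMismatchError(BiovoltError, ValueError):
    """Trace metadata declares units other than microvolts."""


class UnsortedEventsError(BiovoltError, ValueError):
    """An event list is not sorted by onset time."""


class ConfigError(BiovoltError, ValueError):
    """A run configuration is invalid or incomplete."""
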