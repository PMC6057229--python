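"""Exception types shared across the toolbox."""


class TopostatError(Exception):
    """Base class for all topostat errors."""


class EpochsFormatError(TopostatError, ValueError):
    """An epochs container is malformed (missing axis, attribute or group)."""


class StructuralError(TopostatError, ValueError):
    """Data blocks are mutually inconsistent (sensor/time axes, missing conditions)."""


class ConditionNotFoundError(TopostatError, KeyError):
    """A requested condition label is absent from the dataset."""


class TimeRangeError(TopostatError, ValueError):
    """A requested time range falls outside the epoch or selects no samples."""


class ParameterError(TopostatError, ValueError):
    """An analysis parameter is out of its valid range."""


class StatisticsError(TopostatError, ValueError):
    """Not enough data to run the requested statistic (e.g. < 2 subjects)."""


class DegenerateTopographyError(TopostatError, ValueError):
    """A topography has zero norm (after optional average referencing)."""


class SampleSizeError(TopostatError, ValueError):
    """Too few trials to build a classification sample set."""


class CapabilityError(TopostatError, ValueError):
    """A result payload is not supported by the requested operation."""
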