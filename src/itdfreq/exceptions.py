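"""Exceptions raised by itdfreq analyses."""


class ItdFreqError(Exception):
    """Base class for itdfreq errors."""


class EmptyResponseError(ItdFreqError):
    """A response contains no spikes after filtering."""


class InsufficientDataError(ItdFreqError):
    """Too few spikes or frequency points for the requested statistic."""


class ConvergenceError(ItdFreqError):
    """A series expansion or optimizer failed to converge."""


class UndefinedStatisticError(ItdFreqError):
    """The statistic is undefined for this input (e.g. zero resultant)."""
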