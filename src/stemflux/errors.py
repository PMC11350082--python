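"""Exception hierarchy for the stem-flux pipeline."""


class StemfluxError(Exception):
    """Base class for all package errors."""


class ConfigError(StemfluxError):
    """Invalid configuration (bad date range, nonpositive step, bad geometry...)."""


class AlignmentError(StemfluxError):
    """Series that must share a timestamp grid do not."""


class InsufficientDataError(StemfluxError):
    """Too few records to perform an operation (fit, baseline, split)."""


class SingularDesignError(StemfluxError):
    """Rank-deficient design: the requested fit is unidentifiable."""


class MonthMissingError(StemfluxError):
    """A month present in the data has no entry in the parameter/truth map."""


class LoadError(StemfluxError):
    """A CSV input violates its declared schema."""
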