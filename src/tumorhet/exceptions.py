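"""Exception hierarchy for tumorhet."""


class TumorhetError(Exception):
    """Base class for all tumorhet errors."""


class TableFormatError(TumorhetError, ValueError):
    """A tabular input does not conform to the expected dialect
    (missing mandatory column, unparseable row, ...)."""


class ValidationError(TumorhetError, ValueError):
    """A record or table violates a domain invariant
    (overlapping segments, CP outside [0, 1], duplicate mutation ids, ...)."""


class ConfigurationError(TumorhetError, ValueError):
    """Inconsistent configuration or simulation parameters
    (e.g. an expected VAF above 1 after the CP->VAF mapping)."""


class MissingPurityError(ValidationError):
    """A sample without tumor purity entered the ITH pipeline; such samples
    must be excluded and reported, mirroring the cohort inclusion rule."""
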