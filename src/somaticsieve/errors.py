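"""Exception types shared across the pipeline stages."""


class SomaticSieveError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(SomaticSieveError):
    """A record violates its invariants (negative depth, bad frequency, unknown label...)."""


class FormatError(SomaticSieveError):
    """An input file does not parse (bad BED interval, missing column...)."""


class WrongVariantClassError(SomaticSieveError):
    """An operation restricted to indels (or SNVs) received the other class."""


class InconclusiveContextError(SomaticSieveError):
    """Flanking sequence context is missing, so a context rule cannot be evaluated.

    Distinct from a filter failure: the cascade reports such records as
    kept-with-warning rather than removed.
    """


class UndefinedAlleleFractionError(SomaticSieveError):
    """Allele fraction requested at a site with zero total depth."""


class ConfigError(SomaticSieveError):
    """A configuration value violates its documented constraints."""


class PipelineStageError(SomaticSieveError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
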