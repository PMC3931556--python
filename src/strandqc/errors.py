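"""Exception hierarchy used across the package."""


class StrandQCError(Exception):
    """Base class for all strandqc errors."""


class FormatError(StrandQCError, ValueError):
    """Input file does not parse as the declared format."""


class ValidationError(StrandQCError, ValueError):
    """A value or record violates a documented contract."""


class UndefinedMetricError(StrandQCError, ValueError):
    """A metric is mathematically undefined for the given input
    (e.g. a strand with zero reads, an empty library, zero variance)."""
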