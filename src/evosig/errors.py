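"""Exception hierarchy.

Everything raised on bad user input derives from :class:`EvosigError` so
CLI entry points can catch one type and exit cleanly.
"""


class EvosigError(Exception):
    """Base class for all package-specific errors."""


class InputError(EvosigError):
    """Missing, empty or unreadable input file."""


class ParseError(EvosigError):
    """File content does not conform to the expected dialect."""


class ValidationError(EvosigError):
    """Data violates a structural invariant (ragged alignment, bad weights...)."""


class ReferenceNotFoundError(EvosigError, KeyError):
    """Requested reference sequence / chain is absent."""


class DegenerateColumnError(EvosigError):
    """All-gap column cannot be profiled without a pseudocount."""


class MappingError(EvosigError):
    """Sequence-to-structure mapping failed or covers too little."""


class ConfigError(EvosigError):
    """Synthetic generator configuration is internally inconsistent."""


class UndefinedMetricError(EvosigError):
    """Metric undefined for this input (single-class AUC, all-tie sign test)."""
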