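"""Exception hierarchy for epitoc.

All validation failures raise a subclass of :class:`EpitocError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class EpitocError(Exception):
    """Base class for all epitoc errors."""


class FormatError(EpitocError):
    """Malformed tabular artifact (duplicate IDs, bad structure)."""


class SchemaError(EpitocError):
    """Required column missing or mis-typed."""


class RangeError(EpitocError):
    """Value outside its permitted range (e.g. beta outside [0, 1])."""


class ValidationError(EpitocError):
    """Semantically invalid content (negative age, empty clock, ...)."""


class InputError(EpitocError):
    """Inputs incompatible with the requested operation."""
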