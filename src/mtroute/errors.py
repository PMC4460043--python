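"""Exception hierarchy for the pipeline.

Validation errors (bad user input, malformed files) derive from
:class:`ValidationError`; everything else that the pipeline raises on
purpose derives from :class:`MtrouteError`.  The CLI maps ValidationError
to exit code 1 and other MtrouteError/unexpected failures to exit code 2.
"""


class MtrouteError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(MtrouteError):
    """Invalid user input: malformed tokens, broken schemas, bad config."""


class VariantParseError(ValidationError):
    """A variant token does not match the rCRS-relative grammar."""


class PositionRangeError(ValidationError):
    """A position lies outside the 1..16569 rCRS coordinate range."""


class SchemaError(ValidationError):
    """A tabular input lacks required columns or has malformed cells."""


class StructureError(ValidationError):
    """A haplogroup tree file contains cycles, orphans or duplicates."""


class ContractViolation(MtrouteError):
    """An operation was called outside its documented precondition."""


class AlignmentError(MtrouteError):
    """A sequence could not be aligned to the reference within bounds."""


class RootingError(MtrouteError):
    """No outgroup node is reachable, so the network cannot be rooted."""
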