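"""Exception hierarchy.

All package errors derive from :class:`CoevomapError` so callers (and the
CLI) can distinguish bad input (:class:`InputError`) from infeasible
instances (:class:`InfeasibleError`).
"""


class CoevomapError(Exception):
    """Base class for all package errors."""


class InputError(CoevomapError):
    """Malformed or inconsistent input data."""


class RaggedAlignmentError(InputError):
    """Alignment rows of unequal width; names the offending sequence."""


class MissingSpeciesError(InputError):
    """A sequence has no species label."""


class DuplicateIdError(InputError):
    """Duplicate sequence identifier within a family."""


class UnknownIdError(InputError):
    """Lookup of a sequence id not present in a family."""


class InfeasibleError(CoevomapError):
    """The instance admits no matching (e.g. no shared species)."""


class TooLargeError(CoevomapError):
    """Exhaustive enumeration would exceed the configured cap."""


class CardinalityError(CoevomapError):
    """A matching does not have the required (maximum) cardinality."""
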