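"""Exception hierarchy for pipeline errors.

All exceptions derive from :class:`UridivError` so callers can catch one
base class; most also derive from the closest builtin (``ValueError`` for
bad values, ``RuntimeError`` for failed procedures).
"""


class UridivError(Exception):
    """Base class for all package errors."""


class FormatError(UridivError, ValueError):
    """A file does not conform to its declared on-disk format."""


class InvariantError(UridivError, ValueError):
    """A domain-type invariant was violated (e.g. asymmetric matrix)."""


class ConfigurationError(UridivError, ValueError):
    """Inconsistent run configuration (e.g. non-prefix-disjoint primers)."""


class ConsistencyError(UridivError, ValueError):
    """Cross-referenced inputs disagree (e.g. hit for an unknown query)."""


class GenerationError(UridivError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
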