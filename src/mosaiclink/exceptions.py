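"""Exception hierarchy.

All package errors derive from :class:`MosaiclinkError` so callers can catch
one base class; the mixed-in builtin (ValueError / RuntimeError) preserves
idiomatic behaviour for code that does not know about the package.
"""


class MosaiclinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(MosaiclinkError, ValueError):
    """A simulation/analysis design that makes the requested statistic undefined
    (e.g. fewer than two half-sib offspring for pair-sharing statistics)."""


class DomainError(MosaiclinkError, ValueError):
    """A parameter outside its mathematical domain (proportions outside [0, 1], ...)."""


class ReferenceMismatchError(MosaiclinkError, RuntimeError):
    """The reference base at a variant position disagrees with the variant's REF
    allele: the variant file and reference sequence are out of sync."""


class InconsistentTallyError(MosaiclinkError, ValueError):
    """Breeding-outcome counts violate one of the tally identities; the message
    names the failing identity."""


class UndefinedStatisticError(MosaiclinkError, ValueError):
    """A statistic that cannot be computed from the given data (zero variance,
    empty sample, zero depth...)."""


class ConfigError(MosaiclinkError, ValueError):
    """An unparseable or invalid run configuration."""
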