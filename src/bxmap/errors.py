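"""Exception hierarchy shared across bxmap modules."""


class BxmapError(Exception):
    """Base class for all bxmap errors."""


class DomainError(BxmapError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UsageError(BxmapError, ValueError):
    """Operations combined in an unsupported way (e.g. markers on two chromosomes)."""


class ParseError(BxmapError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class UndefinedTestError(DomainError):
    """A statistical test was requested on zero observations."""


class NoConsistentIntervalError(BxmapError):
    """No chromosomal position is consistent with every retained individual.

    Raised by localization when the constraint intersection is empty after
    contradictory individuals have been excluded — a model violation
    (mis-phenotyping, pervasive genotyping error, or wrong chromosome).
    """
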