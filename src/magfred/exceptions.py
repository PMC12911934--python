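"""Exception hierarchy for the pipeline."""


class MagfredError(Exception):
    """Base class for all package errors."""


class ValidationError(MagfredError):
    """Input data violates a documented contract (negative counts, bad enums, ...)."""


class CommunityUndefinedError(MagfredError):
    """A community has fewer than two members, so pairwise redundancy is undefined."""


class UndefinedStatisticError(MagfredError):
    """A statistic is mathematically undefined for the given input (e.g. zero variance)."""
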