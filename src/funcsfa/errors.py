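"""Exception hierarchy used across the package."""


class FuncSFAError(Exception):
    """Base class for all funcsfa errors."""


class FormatError(FuncSFAError):
    """A file did not conform to the expected dialect."""


class ValidationError(FuncSFAError):
    """An in-memory object violated one of its invariants."""


class SingularPosteriorError(FuncSFAError):
    """The posterior precision matrix could not be inverted.

    Surfaced instead of silently regularizing: a singular posterior
    indicates non-finite inputs or a degenerate model state.
    """


class ZeroVarianceFactorError(FuncSFAError):
    """A factor column of E[Z|X] has (numerically) zero sample variance,
    so the unit-variance rescaling is undefined."""
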