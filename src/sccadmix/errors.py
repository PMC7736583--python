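"""Exception hierarchy.

All package-raised errors derive from :class:`SccadmixError` so callers can
catch everything in one clause; the subclasses distinguish bad arguments,
degenerate inputs (formally valid but analytically meaningless), and
configuration problems.
"""


class SccadmixError(Exception):
    """Base class for all errors raised by sccadmix."""


class InvalidArgumentError(SccadmixError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SccadmixError, ValueError):
    """Input is structurally valid but the requested quantity is undefined
    (e.g. all variants monomorphic, zero denominator)."""


class ConfigError(SccadmixError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class ValidationError(SccadmixError, ValueError):
    """Data fails an internal consistency check (e.g. probabilities that do
    not sum to one, misaligned sample identifiers)."""
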