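"""Exception hierarchy shared across the analysis stages."""


class MetstabError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MetstabError):
    """A text value could not be parsed; the message names the offending row."""


class IntegrityError(MetstabError):
    """A dataset violates a structural invariant (duplicates, wrong row count)."""


class SpecError(MetstabError):
    """A simulation specification is internally inconsistent."""


class UnbalancedDataError(MetstabError):
    """The factorial layout has unequal cell counts; the message lists cells."""


class ContractError(MetstabError):
    """A precondition of an operation was not met by its inputs."""
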