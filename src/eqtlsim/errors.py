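"""Exception hierarchy used across the package."""


class EqtlSimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EqtlSimError, ValueError):
    """An argument violates an operation's preconditions."""


class CapacityError(EqtlSimError, RuntimeError):
    """Not enough eligible SNPs/genes/samples to satisfy a request."""


class DegenerateInputError(EqtlSimError, ValueError):
    """Input is constant/zero-variance where variation is required."""


class AlignmentError(EqtlSimError, ValueError):
    """Two data structures do not share a compatible sample or id set."""


class ConsistencyError(EqtlSimError, ValueError):
    """Cross-references between objects (gene/SNP ids) do not resolve."""
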