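"""Exception hierarchy used across the package."""


class EcmcommError(Exception):
    """Base class for all package errors."""


class FormatError(EcmcommError):
    """Malformed on-disk input (FASTA/Newick/TSV)."""


class EmptyInputError(EcmcommError):
    """Input file or collection was empty where content is required."""


class ValidationError(EcmcommError):
    """A domain invariant was violated."""


class DegenerateInputError(EcmcommError):
    """Input is structurally valid but the operation is undefined on it."""
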