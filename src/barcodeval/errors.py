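"""Exception hierarchy shared across the package."""


class BarcodevalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BarcodevalError):
    """A file could not be parsed (FASTA, specimen table, config)."""


class ValidationError(BarcodevalError):
    """Input data violated a structural invariant (ids, markers, lengths)."""


class AlignmentError(BarcodevalError):
    """Alignment preconditions violated (empty input, mixed markers)."""


class DistanceError(BarcodevalError):
    """Distance computation preconditions violated."""


class TreeError(BarcodevalError):
    """Tree construction or query failed."""


class NetworkError(BarcodevalError):
    """Haplotype network construction failed."""


class GenerationError(BarcodevalError):
    """A synthetic dataset request could not be satisfied."""


class TruthMismatchError(BarcodevalError):
    """A generated dataset contradicts its own design record."""
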