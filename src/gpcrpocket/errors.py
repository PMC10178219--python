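"""Exception hierarchy shared across the toolkit."""


class GPCRPocketError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GPCRPocketError):
    """A text input does not conform to its declared format."""


class EmptyStructureError(FormatError):
    """A coordinate file contained no usable polymer residues."""


class ResolutionError(GPCRPocketError):
    """A generic residue number could not be resolved to coordinates."""


class DegenerateGeometryError(GPCRPocketError):
    """A point configuration is too degenerate (rank-deficient) to measure."""


class NonRealizableError(GPCRPocketError):
    """An edge-length set does not embed as a tetrahedron in 3-space."""
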