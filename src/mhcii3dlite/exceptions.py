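"""Exception hierarchy for mhcii3dlite."""


class MHCII3DError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(MHCII3DError):
    """Malformed or empty PDB input."""


class GeometryError(MHCII3DError):
    """Degenerate geometry (collinear points, mismatched point sets)."""


class ParameterError(MHCII3DError):
    """Invalid configuration parameter."""


class CompileError(MHCII3DError):
    """Statistical scoring function could not be compiled."""


class PotentialFormatError(MHCII3DError):
    """Potential file is corrupted or has an unsupported version."""


class InputError(MHCII3DError):
    """Invalid domain input (sequence too short, missing chain, bad IC50)."""


class AlleleLookupError(MHCII3DError):
    """No scaffolds available for the requested allele."""


class EvaluationError(MHCII3DError):
    """Undefined evaluation statistic (single-class labels, constant input)."""
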