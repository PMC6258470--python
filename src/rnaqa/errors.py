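"""Exception hierarchy for rnaqa."""


class RnaQaError(Exception):
    """Base class for all rnaqa errors."""


class PdbParseError(RnaQaError):
    """Raised when a PDB file cannot be parsed into an RNA structure."""


class PropertyError(RnaQaError):
    """Raised when atomic mass/charge assignment fails."""


class FrameError(RnaQaError):
    """Raised when a nucleotide lacks one of the frame-defining atoms."""


class DegenerateFrameError(FrameError):
    """Raised when the frame-defining atoms are (nearly) colinear."""


class VoxelizationError(RnaQaError):
    """Raised when an atom falls outside the featurization cube."""


class LabelingError(RnaQaError):
    """Raised when an unfitness label or RMSD cannot be computed."""


class ModelError(RnaQaError):
    """Raised for invalid network specifications or inputs."""


class ShapeError(ModelError):
    """Raised when a layer stack produces an invalid spatial shape."""


class AssessmentError(RnaQaError):
    """Raised when a structure yields no scoreable nucleotide."""


class EvaluationError(RnaQaError):
    """Raised for invalid decoy sets or degenerate metric inputs."""
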