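"""Named exceptions raised across the pipeline.

Every rejection contract in the package raises one of these, so callers
(and the CLI) can distinguish malformed input from genuine bugs.
"""


class RemcpmError(Exception):
    """Base class for all package errors."""


class UnknownGroupError(RemcpmError):
    """Group label outside {FS, early_dep, late_dep}."""


class HypnogramError(RemcpmError):
    """Invalid hypnogram content (empty, bad alphabet, bad epoch length)."""


class UnknownStageError(HypnogramError):
    """Stage symbol outside {W, N1, N2, N3, R}; carries the offending line."""


class HypnogramFormatError(HypnogramError):
    """Malformed hypnogram file: missing metadata or non-contiguous index."""


class SplitError(RemcpmError):
    """Segmentation clock time outside the recording window or degenerate."""


class ParcellationError(RemcpmError):
    """Invalid node -> network assignment."""


class ZeroVarianceNodeError(RemcpmError):
    """A node time series has zero variance; names the node."""


class MatrixFormatError(RemcpmError):
    """Connectivity matrix not square / not numeric / wrong dimension."""


class AsymmetryError(MatrixFormatError):
    """Matrix asymmetry exceeds the symmetrization tolerance."""


class EdgeVectorError(RemcpmError):
    """Edge-vector length is not a triangular number n*(n-1)/2."""


class ConstantBehaviorError(RemcpmError):
    """Behavior vector has zero variance; correlation-based steps undefined."""


class EmptyMaskError(RemcpmError):
    """Operation requires at least one consensus edge."""


class BehaviorTableError(RemcpmError):
    """Behavior CSV missing columns, duplicate subjects, or unknown groups."""


class ConfigError(RemcpmError):
    """Invalid configuration value."""


class StageError(RemcpmError):
    """Pipeline stage failure; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
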