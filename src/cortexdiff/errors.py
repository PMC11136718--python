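"""Exception hierarchy for cortexdiff."""


class CortexDiffError(Exception):
    """Base class for all package errors."""


class ConfigError(CortexDiffError):
    """Invalid simulation or analysis configuration."""


class AtlasError(CortexDiffError):
    """Invalid atlas definition or sizing problem."""


class GridMismatchError(CortexDiffError):
    """Two volumes that must share a voxel grid do not."""


class MaskError(CortexDiffError):
    """A lesion mask is not binary or otherwise malformed."""


class EmptyRegionError(CortexDiffError):
    """A region's partial-volume weights sum to zero."""


class EmptyNetworkError(CortexDiffError):
    """A network has no voxels, so a fraction is undefined."""


class InsufficientDataError(CortexDiffError):
    """Too few subjects or observations for the requested fit."""


class UnclassifiableError(CortexDiffError):
    """Too few available cognitive domains to assign a phenotype."""


class DegenerateDataError(CortexDiffError):
    """Degenerate input for a statistical test (e.g. zero variance)."""


class ConvergenceError(CortexDiffError):
    """An iterative model fit failed to converge (e.g. separation)."""


class PipelineError(CortexDiffError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
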