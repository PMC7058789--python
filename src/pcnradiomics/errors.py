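"""Exception types raised across the pipeline.

Every stage signals malformed input with one of these rather than a bare
ValueError, so the orchestrator can report which contract was violated.
"""


class InvalidArgumentError(ValueError):
    """A parameter is outside its documented domain (non-positive spacing, ...)."""


class IncompatibleGridError(ValueError):
    """Volume and mask do not live on the same voxel lattice."""


class EmptyRoiError(ValueError):
    """A mask contains no foreground voxels (possibly after resampling)."""


class NoPairsError(ValueError):
    """A co-occurrence matrix was requested for an ROI with no voxel pairs."""


class InvalidLabelsError(ValueError):
    """Class labels unusable for the requested operation (e.g. a single class)."""


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero row or column."""


class StratificationError(ValueError):
    """A stratified split or fold cannot represent every class."""


class TrainingFailureError(RuntimeError):
    """An optimizer failed to converge; carries the best-effort model if any."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model
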