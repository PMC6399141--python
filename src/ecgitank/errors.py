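"""Exception hierarchy shared across the pipeline stages."""


class EcgiTankError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcgiTankError, ValueError):
    """A configuration or call parameter violates its precondition."""


class ContainmentError(EcgiTankError):
    """A surface that must enclose another fails to do so."""


class UnreachableVertexError(EcgiTankError):
    """Activation cannot reach every vertex (disconnected mesh)."""


class OverlapError(EcgiTankError):
    """Action potential duration exceeds the pacing cycle length."""


class ConfigurationError(EcgiTankError):
    """Inconsistent module configuration (e.g. empty local neighbourhood)."""


class EmptyViewError(EcgiTankError):
    """The camera frustum contains no part of the heart surface."""


class DegenerateCameraError(EcgiTankError, ValueError):
    """Camera position and focal centre coincide."""


class CostUndefinedError(EcgiTankError):
    """An alignment cost has no valid correspondences to average over."""


class OptimizationFailureError(EcgiTankError):
    """All optimizer starts failed to reduce the cost."""


class EmptyMaskError(EcgiTankError):
    """Amplitude thresholding removed every pixel."""


class SyncError(EcgiTankError):
    """No rising edge found in the camera-sync channel."""


class InsufficientBeatsError(EcgiTankError):
    """Fewer pacing cycles detected than requested for averaging."""


class DataQualityError(EcgiTankError):
    """Bad-channel screening flagged more than half the channels."""


class GeometryError(EcgiTankError):
    """Fictitious-source construction violated containment."""


class SingularKernelError(EcgiTankError):
    """An evaluation point coincides with a fictitious source."""


class IllConditioningError(EcgiTankError):
    """Forward collocation residual exceeded the hard tolerance."""


class ReconstructionRefusedError(EcgiTankError):
    """Too many invalid tank channels to attempt an inverse solution."""


class ComponentError(EcgiTankError):
    """Delay graph disconnected after unreliable edges were dropped."""


class PairingError(EcgiTankError):
    """No electrode/node could be paired with an in-mask pixel."""


class RoiError(EcgiTankError):
    """Region of interest does not intersect the valid data mask."""


class StageError(EcgiTankError):
    """A pipeline stage failed; message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
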