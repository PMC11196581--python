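"""Exception hierarchy for the sweetmsm pipeline."""


class SweetMSMError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(SweetMSMError):
    """A configuration value violates a structural constraint."""


class InvalidParameterError(SweetMSMError):
    """A function argument is outside its admissible range."""


class IntegrationUnstableError(SweetMSMError):
    """Langevin integration left the guarded domain."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class EmbeddingError(SweetMSMError):
    """A latent collective variable cannot be realized as 3-D coordinates."""


class TopologyLookupError(SweetMSMError):
    """A residue or atom referenced by name/id does not exist in the topology."""


class DegenerateGeometryError(SweetMSMError):
    """Coincident atoms make a distance-based quantity undefined."""


class EstimationError(SweetMSMError):
    """Markov model estimation failed (e.g. empty connected set)."""


class GridMismatchError(SweetMSMError):
    """Two landscape grids do not share a common binning."""


class EmptyLandscapeError(SweetMSMError):
    """No finite bin exists on a landscape."""


class NoMinimaError(SweetMSMError):
    """A landscape has no local free-energy minimum."""


class DisconnectedError(SweetMSMError):
    """Two landscape states are not connected through finite bins."""


class UnderdeterminedFitError(SweetMSMError):
    """Too few atoms to determine a rigid superposition."""


class SingularGeometryError(SweetMSMError):
    """Zero interatomic distance in an interaction-energy sum."""
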