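"""Exception types raised across the pipeline."""


class NeurorgError(Exception):
    """Base class for all package errors."""


class GeometryError(NeurorgError):
    """Requested neuron geometry is infeasible within the frame."""


class TrackPlacementError(NeurorgError):
    """Planted trajectories cannot be realised (distance unreachable or no room)."""


class PackingError(NeurorgError):
    """Requested spot/contact planting is infeasible in the target region."""


class NoSomaFound(NeurorgError):
    """Soma detection found no candidate object."""


class EmptyMaskError(NeurorgError):
    """Detection was asked to run with an empty analysis mask."""


class TrackOutsideMaskError(NeurorgError):
    """A track sample could not be located inside the neurite mask."""


class UndefinedFractionError(NeurorgError):
    """Contact fraction requested with zero peroxisomes in the analysis region."""


class KymographError(NeurorgError):
    """Kymograph path exits the frame or is otherwise invalid."""


class ConfigError(NeurorgError):
    """Run configuration failed validation."""


class FixtureIOError(NeurorgError):
    """Reading or writing a fixture directory failed."""
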