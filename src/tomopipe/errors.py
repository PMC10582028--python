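"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`TomopipeError`
so batch drivers can distinguish expected failures from bugs.
"""


class TomopipeError(Exception):
    """Base class for all tomopipe errors."""


class FormatError(TomopipeError):
    """A file on disk violates its format contract (bad header, ragged table...)."""


class ConfigError(TomopipeError):
    """Configuration is invalid: unknown module/key, type mismatch, missing section."""


class GeometryError(TomopipeError):
    """Invalid rotation/orientation input (improper matrix, bad symmetry label...)."""


class SimulationError(TomopipeError):
    """Infeasible or invalid synthetic-data request."""


class EstimationError(TomopipeError):
    """A fit/estimate could not be produced (flat spectrum, empty mask...)."""


class PipelineError(TomopipeError):
    """Workflow-engine level failure (unknown module, missing watch dir...)."""
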