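"""Exception hierarchy for the dais pipeline."""


class DaisError(Exception):
    """Base class for all dais errors."""


class FormatError(DaisError):
    """Input file could not be parsed or is internally inconsistent."""


class InsufficientFramesError(FormatError):
    """An ensemble needs at least two frames to be a trajectory."""


class IncompatibleEnsemblesError(DaisError):
    """Case and Control ensembles do not share the required residue universe."""


class IncompatibleTracksError(DaisError):
    """Tracks being paired were not built from a shared CA selection."""


class DegenerateInputError(DaisError):
    """Geometry is too degenerate for the requested computation."""


class DegenerateTrackError(DaisError):
    """A feature track cannot be normalized (initial polar distance ~ 0)."""


class NotScoreableError(DaisError):
    """A feature or track pair cannot be scored (infinite death, no overlap)."""


class InvalidFeatureError(DaisError):
    """A persistence feature violates its invariants (e.g. empty generators)."""


class NoHydrogensError(DaisError):
    """Hydrogen-bond detection requires explicit hydrogens in the ensemble."""


class ConfigError(DaisError):
    """A configuration value violates its contract."""
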