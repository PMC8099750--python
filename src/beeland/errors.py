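"""Exception hierarchy shared across the pipeline."""


class BeelandError(Exception):
    """Base class for all package errors."""


class ParameterError(BeelandError, ValueError):
    """A numeric parameter violates its documented domain."""


class FormatError(BeelandError, ValueError):
    """An input file does not conform to the expected schema."""


class TrackValidationError(BeelandError, ValueError):
    """A single track violates a structural invariant (metadata, sampling)."""


class TrackRejectedError(BeelandError, ValueError):
    """A track cannot be processed (e.g. shorter than the smoothing window).

    Carries ``track_id`` so callers can log which maneuver was dropped.
    """

    def __init__(self, track_id: str, reason: str):
        self.track_id = track_id
        self.reason = reason
        super().__init__(f"track {track_id!r} rejected: {reason}")


class ModelSpecError(BeelandError, ValueError):
    """The requested statistical model is not estimable from the data given."""


class DegenerateFitError(BeelandError, ValueError):
    """Input data admit no meaningful fit (e.g. zero variance)."""


class TrackTooLongError(BeelandError, ValueError):
    """Brute-force enumeration refused: quadratic cost would be excessive."""
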