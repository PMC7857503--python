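"""Exception hierarchy.

Every anticipated failure mode maps to a subclass of :class:`LipbindError`
so the CLI can translate them into stable exit codes (config errors vs fit
failures vs data-format errors).
"""


class LipbindError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipbindError):
    """Invalid configuration, missing inputs, or unknown identifiers."""


class InvalidArgumentError(LipbindError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(LipbindError):
    """Too few points/frames/poses to perform the requested analysis."""


class AlignmentError(LipbindError):
    """Curves or traces do not share a compatible grid."""


class FitFailureError(LipbindError):
    """Least-squares optimisation did not converge.

    Carries the underlying optimiser diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: object = None):
        super().__init__(message)
        self.diagnostics = diagnostics


class NonPositivePartitionError(LipbindError):
    """IC50 <= K_I: membrane binding indistinguishable from inhibitor affinity."""


class NonPositiveRateError(LipbindError):
    """k_obs <= k_off: no positive association rate can be inferred."""


class DegenerateAmplitudeError(LipbindError):
    """Normalisation requested with zero total amplitude."""


class MissingSelectionError(LipbindError):
    """A required atom/residue selection matched nothing in the frame."""


class MissingAtomError(MissingSelectionError):
    """A specific named atom is absent from the requested residue."""


class DegenerateGeometryError(LipbindError):
    """Zero-length vector or otherwise undefined geometric quantity."""


class EmptyWindowError(LipbindError):
    """A time window selects no frames."""


class SequenceError(LipbindError):
    """Invalid peptide sequence or modification site."""


class MassLookupError(LipbindError):
    """Unknown element or residue in a mass computation."""


class GenerationError(LipbindError):
    """Synthetic-data generator produced an inconsistent layout."""
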