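"""Exception hierarchy for the myelination-screen pipeline."""


class MyeliscreenError(Exception):
    """Base class for all package errors."""


class FormatError(MyeliscreenError):
    """An image or table does not have the expected structure."""


class LayoutError(MyeliscreenError):
    """A plate layout violates the screening plate design."""


class GenerationError(MyeliscreenError):
    """A synthetic field could not be generated (e.g. infeasible packing)."""


class UndefinedScoreError(MyeliscreenError):
    """A score denominator is zero; the field is unusable, not scored 0."""


class QCError(MyeliscreenError):
    """Plate quality control cannot be computed (e.g. missing controls)."""


class NoFitError(MyeliscreenError):
    """Dose-response data carry no fittable signal (e.g. flat responses)."""
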