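"""Exception hierarchy for the screening pipeline."""


class DspError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(DspError):
    """Structural problem in a library, layout, plate or manifest file."""


class QCError(DspError):
    """Control wells missing or degenerate; plate cannot be normalized."""


class FitError(DspError):
    """Dose-response points unusable for curve fitting."""


class ScoringError(DspError):
    """Invalid inputs to DSS / quantile / agreement computations."""
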