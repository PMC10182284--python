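"""Exception types raised by the rotary-trace data model and analyses."""


class F1RotaryError(Exception):
    """Base class for all package-specific errors."""


class MissingColumnError(F1RotaryError):
    """A required column is absent from an input table."""


class NonUniformSamplingError(F1RotaryError):
    """Time stamps are not uniformly spaced within tolerance."""


class NonNumericDataError(F1RotaryError):
    """A cell that must be numeric could not be parsed as a number."""


class DegenerateGeometryError(F1RotaryError):
    """Centroid geometry admits no polar angle (all points at the center)."""


class FitError(F1RotaryError):
    """A model fit failed (non-convergence, rank deficiency, bad estimates)."""
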