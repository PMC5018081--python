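"""Exception types raised across the pipeline."""


class CapmotionError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CapmotionError, ValueError):
    """A table is missing a required column or carries an invalid one."""


class ParseError(CapmotionError, ValueError):
    """A table cell could not be parsed (reported with its row number)."""


class ValidationError(CapmotionError, ValueError):
    """A dataset violates an invariant (duplicate keys, non-finite coordinates, ...)."""


class MissingTipError(CapmotionError, LookupError):
    """No tip information exists for a crop/time step where a cell needs it."""


class CorrectionError(CapmotionError, ValueError):
    """Drift correction cannot proceed for an interval (no usable tip track)."""


class FitError(CapmotionError, RuntimeError):
    """Model fitting failed or did not converge."""
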