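"""Exception and warning types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateRoiError(ValueError):
    """An ROI operation produced an empty or unusable mask."""


class OutOfBoundsError(ValueError):
    """A geometric operation would leave the image grid."""


class DegenerateGlcmError(ValueError):
    """No valid pixel pair exists for the requested GLCM displacement."""


class DegenerateRlmError(ValueError):
    """A run-length matrix contains no runs."""


class GenerationError(RuntimeError):
    """The synthetic-cohort generator could not satisfy its geometry
    constraints (e.g. minimum ROI size)."""


class MaskDisagreementWarning(UserWarning):
    """Baseline WMH extends outside the follow-up WMH during subtraction."""


class DegenerateFeatureWarning(UserWarning):
    """A texture feature was undefined on this input and is flagged."""
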