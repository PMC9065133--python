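"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A configuration or function parameter is outside its valid range."""


class InputError(ValueError):
    """An input object (trace, image, file) is malformed or unusable."""


class UnknownPresetError(KeyError):
    """Requested simulation preset name is not defined."""


class EmptyCohortError(ValueError):
    """A per-condition summary was requested for a cohort with no included traces."""
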