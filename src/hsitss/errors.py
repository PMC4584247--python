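"""Exception types shared across the pipeline stages."""


class DegenerateReferenceError(ValueError):
    """White and dark reference frames coincide at some pixel/band."""


class EmptySelectionError(ValueError):
    """A band-cropping window retains no bands."""


class EmptyROIError(ValueError):
    """A mask contains no foreground pixels."""


class DegenerateResponseError(ValueError):
    """The response vector has zero variance and cannot be regressed on."""


class NumericallySingularError(ValueError):
    """A kernel system is numerically singular; carries a condition estimate."""

    def __init__(self, message: str, condition: float):
        super().__init__(f"{message} (condition number ~{condition:.3e})")
        self.condition = condition


class WavelengthMismatchError(ValueError):
    """A model wavelength is farther from every grid band than half a grid step."""
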