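"""Exception types shared across the pipeline."""


class SoftParseError(ValueError):
    """A GDS SOFT file violates the expected structure.

    Parameters
    ----------
    line : int
        1-based line number of the offending line (0 when the problem is
        file-level, e.g. a missing ``^DATASET`` block).
    message : str
        Description of the defect.
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class StateError(RuntimeError):
    """An operation was applied to a matrix in the wrong processing state."""


class FitError(RuntimeError):
    """The noise model could not be fitted (e.g. no low-intensity mode)."""


class ParameterError(ValueError):
    """A numeric parameter is outside its documented range."""
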