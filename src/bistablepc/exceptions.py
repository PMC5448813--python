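"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or procedure parameter is outside its admissible range."""


class DataError(ValueError):
    """Input data are malformed or inconsistent with the session timeline."""


class ConvergenceError(RuntimeError):
    """An optimisation failed on every attempted start."""
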