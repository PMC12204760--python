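"""Exception hierarchy."""


class FraclocError(Exception):
    """Base class for all fracloc errors."""


class FormatError(FraclocError, ValueError):
    """Malformed or inconsistent input data (missing columns, bad values)."""


class DegenerateDataError(FraclocError, ValueError):
    """Input is valid but degenerate for the requested computation."""


class ModelError(FraclocError, RuntimeError):
    """Model fitting or diagnostic failure."""
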