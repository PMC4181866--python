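"""Exception types shared across the package."""


class LocsrrError(Exception):
    """Base class for package-specific errors."""


class CoverageError(LocsrrError, ValueError):
    """A volume of interest falls (entirely) outside an acquisition's FOV."""


class DegenerateGeometryError(LocsrrError, ValueError):
    """Geometric configuration carries no usable information (e.g. parallel
    views, collinear landmarks)."""


class DegenerateInputError(LocsrrError, ValueError):
    """Input data is degenerate for the requested operation (e.g. an
    all-zero stack passed to bias-field correction)."""


class FormatError(LocsrrError, ValueError):
    """A file could not be parsed in the expected format."""


class UnsupportedOrientationError(FormatError):
    """A volume's affine is not axis-aligned."""
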