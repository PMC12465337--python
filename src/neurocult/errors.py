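"""Exception types shared across the package."""


class NeurocultError(Exception):
    """Base class for package errors."""


class ParameterError(NeurocultError, ValueError):
    """An input parameter is out of its documented range.

    The message always names the offending field.
    """


class ShapeMismatchError(NeurocultError, ValueError):
    """Two grids that must share a shape do not; message carries both shapes."""


class PlatemapError(NeurocultError, KeyError):
    """A well is present on disk but missing from the platemap."""
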