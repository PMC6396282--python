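"""Exception types shared across the package."""


class MelanocycleError(Exception):
    """Base class for package errors."""


class ConfigurationError(MelanocycleError, ValueError):
    """A parameter or protocol value is invalid (negative rate, overlap, ...)."""


class StabilityError(MelanocycleError, ValueError):
    """Integration step too coarse for the fastest kinetic rate."""


class InputError(MelanocycleError, ValueError):
    """Malformed or insufficient input data (traces, tables, files)."""
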