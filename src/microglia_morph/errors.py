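"""Exception types shared across the pipeline."""


class MicrogliaMorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MicrogliaMorphError):
    """Invalid configuration: bad channel map, inconsistent parameters."""


class DegenerateInputError(MicrogliaMorphError):
    """Input on which the requested quantity is mathematically undefined
    (constant patch for Otsu, empty mask for a perimeter, ...)."""


class PackingError(MicrogliaMorphError):
    """Synthetic cells could not be placed at the requested separation."""
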