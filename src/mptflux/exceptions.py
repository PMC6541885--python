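"""Exception types shared across the package."""


class FluxDataError(ValueError):
    """Malformed or unusable flux input data."""


class InsufficientDataError(FluxDataError):
    """Too few usable records for the requested operation."""
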