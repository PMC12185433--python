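"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A configuration or model parameter is outside its valid domain."""


class InvalidGeometryError(ValueError):
    """Cell layout is impossible: overlapping somata or out-of-frame placement."""


class InvalidRoiError(ValueError):
    """An ROI cannot be constructed (center outside image, empty mask, duplicate)."""


class InvalidDesignError(ValueError):
    """A statistical design is incomplete or degenerate (missing cells x window entries)."""


class InsufficientSampleError(ValueError):
    """Too few observations for the requested test."""
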