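"""Errors raised across the fusion pipeline."""


class DimensionError(ValueError):
    """Two images that must be co-registered do not share a shape, or an
    image is too small for the requested operation."""


class FormatError(ValueError):
    """An input file has an unsupported pixel layout (e.g. CMYK)."""
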