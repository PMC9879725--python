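"""Exception hierarchy shared across the package."""


class VariantError(ValueError):
    """Base class for all variant-domain errors."""


class ParseError(VariantError):
    """A variant description could not be parsed."""

    def __init__(self, message: str, text: str | None = None):
        super().__init__(message)
        self.text = text


class UnsupportedVariantError(ParseError):
    """A syntactically recognizable but unsupported HGVS feature
    (dup, inv, repeats, uncertain positions, non-genomic coordinates)."""


class PositionError(VariantError):
    """An operation position falls outside the reference sequence."""


class EmptyVariantError(VariantError):
    """The observed sequence equals the reference; relations and
    influence intervals are undefined for empty variants."""


class EnumerationCapError(RuntimeError):
    """The number of minimal representations exceeds the requested cap,
    signalling exponential blowup; use the element set instead."""


class SizeGuardError(RuntimeError):
    """An input exceeds the deliberate size guard of the brute-force oracle."""
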