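"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or frame does not conform to the expected schema."""


class ValidationError(ValueError):
    """Data violate a structural invariant (roles, duplicates, ranges)."""


class DegenerateDataError(ValueError):
    """An operation received data it cannot act on (zero variance, too few points)."""
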