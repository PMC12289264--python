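"""Exception and warning types."""


class DalkSizerError(ValueError):
    """Base class for all computation errors raised by this package."""


class DomainError(DalkSizerError):
    """An input is outside the mathematical domain (e.g. non-positive
    keratometry, zero trephine diameter)."""


class GeometryError(DalkSizerError):
    """The requested configuration is geometrically impossible on the
    spherical cornea (e.g. trephine wider than the corneal diameter, or a
    target arc longer than a semicircle)."""


class ClinicalRangeWarning(UserWarning):
    """Inputs are mathematically valid but outside the clinically validated
    envelope of the recommendation table."""
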