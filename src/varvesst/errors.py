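"""Exception types shared across the package."""


class FormatError(ValueError):
    """A delimited-text input does not match the declared layout."""


class ValidationError(ValueError):
    """Input data violate a documented invariant (range, sign, ordering)."""


class ConfigError(ValueError):
    """A configuration value is outside its admissible range."""


class NoThresholdError(RuntimeError):
    """No greyscale threshold satisfies the season-split constraints."""


class NoSignificantPeakError(RuntimeError):
    """No spectral peak exceeds the false-alarm level in the requested band."""
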