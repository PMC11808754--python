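"""Exception hierarchy for the Fast-Pass pipeline."""


class FastPassError(Exception):
    """Base class for all pipeline errors."""


class LayoutError(FastPassError):
    """Invalid or infeasible spot-array geometry."""


class FormatError(FastPassError):
    """Unreadable or unsupported input file."""


class FormulaError(FastPassError):
    """Molecular formula that cannot be interpreted."""


class AdductError(FastPassError):
    """Unsupported adduct label."""


class ProfileError(FastPassError):
    """Unknown intra-spot spatial profile kind."""


class CalibrationError(FastPassError):
    """Lock-mass correction could not be established."""


class NormalizationError(FastPassError):
    """Spatial normalization is undefined (zero reference signal)."""


class QuantError(FastPassError):
    """Spot integration / ratio / table arithmetic error."""


class StatsError(FastPassError):
    """Statistical routine given degenerate input."""


class ConfigError(FastPassError):
    """Invalid run configuration."""
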