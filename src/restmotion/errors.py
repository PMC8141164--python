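"""Exception hierarchy shared across the pipeline stages."""


class RestmotionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RestmotionError):
    """Invalid parameter or configuration value."""


class ShapeError(RestmotionError):
    """Input of wrong length, shape, or emptiness."""


class ParseError(RestmotionError):
    """Malformed recording file; message names the offending line."""


class DataError(RestmotionError):
    """Invalid data content (missing values, unknown labels)."""


class SchemaError(RestmotionError):
    """Column names/order do not match what a fitted model expects."""


class FitError(RestmotionError):
    """Training precondition violated (single class, k too large)."""


class SplitError(RestmotionError):
    """Subject split cannot satisfy stratification constraints."""


class RankingError(RestmotionError):
    """Feature ranking precondition violated (e.g. single class)."""
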