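"""Exception hierarchy for qpcrvar.

All errors derive from :class:`QpcrVarError` so callers can catch the
package's failures with a single except clause; each subclass maps to one
stage of the pipeline.
"""


class QpcrVarError(Exception):
    """Base class for all qpcrvar errors."""


class ParameterError(QpcrVarError, ValueError):
    """An invalid simulation-design or configuration field; names the field."""


class CalibrationError(QpcrVarError, ValueError):
    """Standard curve unusable (e.g. non-negative slope)."""


class QuantificationError(QpcrVarError, ValueError):
    """Invalid quantity input to a derived-measure computation."""


class PairingError(QpcrVarError, ValueError):
    """ND1/B2M wells could not be matched across a plate pair."""


class NormalizationError(QpcrVarError, ValueError):
    """Reference sample missing where reference normalisation is required."""


class SchemaError(QpcrVarError, ValueError):
    """A data table is missing required columns; names the column."""


class ConfigurationError(QpcrVarError, ValueError):
    """A run-configuration value outside its documented range."""
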