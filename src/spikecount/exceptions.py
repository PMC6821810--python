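"""Exception hierarchy for spikecount.

All errors derive from :class:`SpikeCountError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class SpikeCountError(Exception):
    """Base class for all spikecount errors."""


class InvalidParameterError(SpikeCountError, ValueError):
    """A model parameter violates its domain (e.g. non-positive molar weight)."""


class InvalidMeasurementError(SpikeCountError, ValueError):
    """A methylation value lies outside [0, 1] or cannot be parsed."""


class UndefinedMixtureError(SpikeCountError, ValueError):
    """Mixture with zero cells and zero reference copies has no methylation."""


class InvalidContextError(SpikeCountError, ValueError):
    """A mixture context is unusable (e.g. zero reference copies for inversion)."""


class SaturationError(SpikeCountError, ValueError):
    """A saturated/unbounded estimate was used where a finite count is required."""


class CalibrationSeparationError(SpikeCountError, ValueError):
    """Pure-plasmid methylation does not lie strictly below pure-genomic."""


class InsufficientDataError(SpikeCountError, ValueError):
    """Too few usable points for the requested statistic."""


class InvalidDesignError(SpikeCountError, ValueError):
    """A simulation design violates its invariants."""


class InvalidSeriesError(SpikeCountError, ValueError):
    """A growth series contains values incompatible with the requested fit."""


class PairingError(SpikeCountError, ValueError):
    """No matched pairs between estimates and chamber counts."""


class EmptyInputError(SpikeCountError, ValueError):
    """No usable rows in the input table."""


class ConfigError(SpikeCountError, ValueError):
    """A run configuration is malformed or inconsistent with the data."""
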