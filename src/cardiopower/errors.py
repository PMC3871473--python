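"""Exception hierarchy shared across the package."""


class CardioPowerError(Exception):
    """Base class for all package errors."""


class UnitError(CardioPowerError):
    """Unknown or unsupported physical unit."""


class FormatError(CardioPowerError):
    """A waveform or beat-table file is malformed."""


class ConfigError(CardioPowerError):
    """Invalid configuration (condition name, multiplier target, ...)."""


class SimulationError(CardioPowerError):
    """The hemodynamic integration failed (divergence, negative volume)."""


class SegmentationError(CardioPowerError):
    """Cycle segmentation could not be performed."""


class CalibrationError(CardioPowerError):
    """Volume-gain calibration is impossible (nonpositive stroke volumes)."""


class DatasetError(CardioPowerError):
    """A dataset directory is missing, empty, or incomplete."""


class FitError(CardioPowerError):
    """A statistical fit is degenerate or did not converge."""
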