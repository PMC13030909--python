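"""Exception hierarchy.

All package-raised errors derive from :class:`ThermoloadError` so callers
(and the CLI) can catch one base class and map it to exit code 2.
"""


class ThermoloadError(Exception):
    """Base class for all errors raised by thermoload."""


class InvalidInputError(ThermoloadError, ValueError):
    """A numeric argument is out of domain (non-finite, wrong sign, ...)."""


class DegenerateDesignError(ThermoloadError, ValueError):
    """An assay does not contain enough distinct temperatures to fit."""


class NonTDTBehaviourError(ThermoloadError, ValueError):
    """A fitted time-temperature slope is non-negative (tolerance does not
    decline with temperature), so the data do not follow a TDT curve."""


class CalibrationError(ThermoloadError, ValueError):
    """Repair calibration was requested for a shape where it is undefined."""


class NoCrossoverError(ThermoloadError, ValueError):
    """The net damage rate does not change sign on the given bracket."""


class ConfigurationError(ThermoloadError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class FormatError(ThermoloadError, ValueError):
    """An input file violates its documented format."""


class IntegrityError(ThermoloadError, ValueError):
    """Output files are missing, partial, or mutually inconsistent."""
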