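"""Exception hierarchy for the pipeline."""


class InhalerSwitchError(Exception):
    """Base class for package errors."""


class ConfigError(InhalerSwitchError, ValueError):
    """Invalid generator or run configuration; message names the field."""


class InputError(InhalerSwitchError, ValueError):
    """Malformed input data (unsorted fills, missing columns, bad values)."""


class EstimationError(InhalerSwitchError, RuntimeError):
    """A model cannot be estimated (no informative patients, empty arm)."""


class ConvergenceError(EstimationError):
    """Iterative fitting failed to converge; carries diagnostics."""


class EmissionsError(InhalerSwitchError, ValueError):
    """Missing emission factor for a dispensed product."""
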