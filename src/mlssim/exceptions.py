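"""Exception hierarchy for mlssim.

``ValueError`` subclasses signal bad arguments; ``DataError`` signals inputs
that are structurally valid but physiologically inconsistent (for example a
post-sprint lactate maximum below the resting value).
"""


class MlssimError(Exception):
    """Base class for all mlssim-specific errors."""


class DataError(MlssimError, ValueError):
    """Input data are inconsistent with the physiology being modelled."""


class NoIrreversibleDeclineError(DataError):
    """A sprint power trace never falls irreversibly below the drop threshold."""


class NoProtocolError(MlssimError, LookupError):
    """No ergometer protocol is defined for the given sex / body-mass / class."""


class ModelDegenerateError(MlssimError, RuntimeError):
    """The production and combustion curves admit no usable crossing."""


class NoSteadyStateError(MlssimError, RuntimeError):
    """Lactate production exceeds maximal combustion at the requested load."""


class CalibrationError(MlssimError, RuntimeError):
    """Constant calibration failed to converge; carries best-found residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class TitrationError(MlssimError, RuntimeError):
    """Constant-load titration found no steady trial; carries the verdicts."""

    def __init__(self, message, verdicts=None):
        super().__init__(message)
        self.verdicts = list(verdicts) if verdicts is not None else []
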