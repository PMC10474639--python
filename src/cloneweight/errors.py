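"""Exception hierarchy for the clone-censor-weight pipeline."""


class CloneWeightError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CloneWeightError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(CloneWeightError):
    """A table is missing a required column or has an invalid value."""


class SimulationError(CloneWeightError):
    """The simulator cannot produce a valid trajectory (e.g. daily exit
    probability reaching 1 after covariate modification)."""


class FittingError(CloneWeightError):
    """A model fit failed."""


class NoCensoringEventsError(FittingError):
    """No artificial censoring occurred in an arm; weights degenerate to 1."""


class SeparationError(FittingError):
    """(Quasi-)complete separation detected during a model fit."""


class ConvergenceError(FittingError):
    """Iterative fit did not converge within the iteration budget."""


class WeightUnderflowError(CloneWeightError):
    """An estimated uncensored probability fell below the configured floor."""


class EstimationError(CloneWeightError):
    """A nonparametric estimation step failed (e.g. negative Aalen-Johansen
    diagonal caused by pathological weights)."""
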