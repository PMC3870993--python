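"""Exception hierarchy.

Undefined statistics are never silently coerced to 0 or NaN: operations
either raise one of these errors or return an explicit ``None`` with a
recorded reason (see :class:`riskstand.data_model.StandardisationResult`).
"""


class RiskStandError(Exception):
    """Base class for all package errors."""


class FormatError(RiskStandError):
    """Input file does not have the required structure (e.g. missing column)."""


class ValidationError(RiskStandError):
    """Input values violate a domain constraint (e.g. event not in {0,1})."""


class EmptyDataError(RiskStandError):
    """No usable rows remain after filtering."""


class SpecificationError(RiskStandError):
    """A model or simulation spec references something the data lacks."""


class ConvergenceError(RiskStandError):
    """Maximum-likelihood fit failed, e.g. under perfect separation."""


class PredictionError(RiskStandError):
    """A record cannot be scored by the model (e.g. unseen factor level)."""


class ParameterError(RiskStandError):
    """An invalid parameter value (e.g. K < 1)."""


class NotComputableError(RiskStandError):
    """A standardised measure is undefined for this centre.

    Carries the centre and, where relevant, the offending category or cell so
    callers can report *why* the measure is undefined — the distinction
    between "undefined" and "zero" is central to fair comparison.
    """

    def __init__(self, message: str, centre_id=None, category=None):
        super().__init__(message)
        self.centre_id = centre_id
        self.category = category
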