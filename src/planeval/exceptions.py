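"""Exception hierarchy for plan-evaluation errors."""


class PlanEvalError(Exception):
    """Base class for all planeval errors."""


class ValidationError(PlanEvalError, ValueError):
    """Invalid data: malformed DVH, bad spec, empty input."""


class DVHFormError(ValidationError):
    """An operation received a DVH in the wrong form (differential vs cumulative)."""


class DomainError(PlanEvalError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class ParameterError(PlanEvalError, ValueError):
    """A tissue parameter is missing or outside its admissible range."""


class MissingStructureError(PlanEvalError, KeyError):
    """A required structure (e.g. the PTV) is absent from a patient record."""


class DegeneratePlanError(PlanEvalError, ValueError):
    """A plan-level quantity is undefined, e.g. CI with no volume at the reference isodose."""


class InsufficientDataError(PlanEvalError, ValueError):
    """A statistical summary was requested on fewer than two observations."""
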