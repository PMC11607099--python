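"""Exception hierarchy shared across the package."""


class ResusflowError(Exception):
    """Base class for all errors raised by resusflow."""


class ModelParseError(ResusflowError):
    """Malformed or out-of-subset model document."""


class UnsupportedElementError(ModelParseError):
    """A BPMN/DMN element outside the supported subset was encountered."""

    def __init__(self, tag: str, context: str = ""):
        self.tag = tag
        msg = f"unsupported element: {tag}"
        if context:
            msg += f" (in {context})"
        super().__init__(msg)


class ExpressionError(ResusflowError):
    """Condition expression or decision cell could not be parsed/evaluated."""


class SerializationError(ResusflowError):
    """Model cannot be serialized (e.g., it has validation issues)."""


class RoutingError(ResusflowError):
    """An exclusive gateway has no satisfiable outgoing flow and no default."""


class FormValidationError(ResusflowError):
    """Submitted form values violate the task's field constraints."""


class UnknownTaskError(ResusflowError):
    pass


class UnknownSignalError(ResusflowError):
    pass


class UnknownModelError(ResusflowError):
    pass


class NoSnapshotError(ResusflowError):
    pass


class ConcurrencyError(ResusflowError):
    """Back-navigation refused because tokens or children were created since
    the last snapshot."""


class TimerNotStartedError(ResusflowError):
    pass


class TypeMismatchError(ResusflowError):
    pass


class DecisionEvaluationError(ResusflowError):
    """Hit-policy violation: no match, or multiple matches under UNIQUE."""


class ScenarioError(ResusflowError):
    pass


class InapplicableInterventionError(ResusflowError):
    """Intervention kind is not applicable to the scenario's injury profile."""


class ContentError(ResusflowError):
    """Bundled clinical content failed to load or cross-validate."""
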