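"""Exception hierarchy for the stereotype-measurement pipeline.

Every failure mode the pipeline can hit on user data gets its own class so
callers can distinguish schema problems (fix the file) from degenerate inputs
(fix the design) without string matching.
"""


class StereolangError(Exception):
    """Base class for all package errors."""


class SchemaError(StereolangError):
    """A file or mapping is missing required fields/columns."""


class ContentError(StereolangError):
    """A file parsed but its content violates an invariant (empty list, duplicates)."""


class FormatError(StereolangError):
    """A data file is malformed at a specific location."""


class OOVError(StereolangError):
    """A lexeme (or one of its component tokens) is absent from an embedding vocabulary."""

    def __init__(self, token: str, model_id: str = ""):
        self.token = token
        self.model_id = model_id
        where = f" in model '{model_id}'" if model_id else ""
        super().__init__(f"token '{token}' is out of vocabulary{where}")


class DegenerateInputError(StereolangError):
    """An input is structurally valid but makes the statistic undefined
    (zero vector, zero variance, empty attribute side)."""


class DesignError(StereolangError):
    """A regression design is unidentifiable (e.g. only one polarity present)."""


class TemplateError(StereolangError):
    """A fill-mask template is missing a required slot."""


class TokenizationError(StereolangError):
    """A target word cannot be scored as a single token by the adapter."""


class ComparabilityError(StereolangError):
    """Two objects measured by different methods were compared directly."""


class InsufficientDataError(StereolangError):
    """Too few observations for the requested estimator."""
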