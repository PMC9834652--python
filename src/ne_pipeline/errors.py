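"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PipelineError):
    """An input table is missing a mandatory column or has a malformed header."""


class ValidationError(PipelineError, ValueError):
    """A record violates one of its documented invariants."""


class DomainError(PipelineError, ValueError):
    """An operation was called with arguments outside its mathematical domain."""


class ConstraintError(PipelineError, ValueError):
    """A simulation configuration is internally infeasible (e.g. target NE above ME)."""
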