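"""Exception hierarchy for the pipeline."""


class MlrkgError(Exception):
    """Base class for all package errors."""


class InputError(MlrkgError):
    """Missing or unreadable input."""


class EncodingError(MlrkgError):
    """Input bytes not decodable as UTF-8; message names the byte offset."""


class ParseError(MlrkgError):
    """Malformed record in a structured file; message carries the line number."""


class ConfigurationError(MlrkgError):
    """Invalid configuration (empty keyword set, infeasible fixture plan, ...)."""


class ValidationError(MlrkgError):
    """Conflicting expert-validation verdicts for one triplet key."""


class ContractError(MlrkgError):
    """A precondition on table contents was violated (e.g. incomplete row)."""


class QueryError(MlrkgError):
    """Invalid distillation query."""
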