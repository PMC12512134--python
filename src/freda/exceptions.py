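"""Exception hierarchy shared across the package."""


class FredaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FredaError):
    """Invalid run configuration or generator specification."""


class ProtocolError(FredaError):
    """A federated protocol invariant was violated (missing seeds, shape
    mismatches between masked payloads, provenance mismatches, ...)."""


class GenerationError(FredaError):
    """Random generation of a mask/matrix failed after the retry budget."""


class NumericalError(FredaError):
    """A numerical routine left its validity envelope (non-PD kernel after
    jitter escalation, strongly negative predictive variance, ...)."""


class TrainingError(FredaError):
    """Local gradient training diverged despite learning-rate backoff."""
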