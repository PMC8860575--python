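"""Exception hierarchy shared across the pipeline stages."""


class SumowavesError(Exception):
    """Base class for all package errors."""


class ValidationError(SumowavesError, ValueError):
    """Malformed input data (bad interval, bad probability, unknown residue...)."""


class ParameterError(SumowavesError, ValueError):
    """Invalid analysis parameter (non-positive dispersion, k > rows, mg <= 0...)."""


class EvidenceError(SumowavesError, ValueError):
    """A record lacks the evidence a rule needs (no MD tag, missing protein context)."""


class EstimationError(SumowavesError, RuntimeError):
    """An estimator is undefined on the given data (e.g. no gene positive in all samples)."""


class ConfigurationError(SumowavesError, ValueError):
    """Invalid or incomplete pipeline configuration."""
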