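"""Exception hierarchy used across the pipeline."""


class KaryonormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KaryonormError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputError(KaryonormError, ValueError):
    """Malformed or inconsistent user input (counts, metadata, coordinates)."""


class NormalizationError(KaryonormError, RuntimeError):
    """Size-factor estimation is impossible (e.g. no gene positive in all libraries)."""


class DegenerateInputError(KaryonormError, RuntimeError):
    """Data do not support the requested operation (e.g. unimodal coverage ratios)."""


class ModelError(KaryonormError, RuntimeError):
    """Statistical model cannot be fit (e.g. fewer than two replicates per group)."""
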