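"""Exception hierarchy for the toolkit.

Everything user-facing derives from :class:`CrisprMcaError` so the CLI can
map library failures to a "user error" exit code while genuine bugs
propagate as internal errors.
"""


class CrisprMcaError(Exception):
    """Base class for all errors raised by this package."""


class InvalidAlphabetError(CrisprMcaError):
    """A sequence contains a symbol outside {A, C, G, T, _} (after U->T)."""


class PairValidationError(CrisprMcaError):
    """A guide/target record violates the pair invariants."""


class DatasetFormatError(CrisprMcaError):
    """A dataset, score-table or candidate file is malformed."""


class UnsupportedSchemeError(CrisprMcaError):
    """An encoding scheme cannot represent the given input (e.g. gaps in C1)."""


class UndefinedRatioError(CrisprMcaError):
    """Imbalance ratio requested for a dataset with no positive samples."""


class UndefinedMetricError(CrisprMcaError):
    """A ranking metric (ROC-AUC / PR-AUC) is undefined, e.g. single-class labels."""


class ConfigurationError(CrisprMcaError):
    """A model / score-table / run configuration is inconsistent or incomplete."""


class SimulationError(CrisprMcaError):
    """The synthetic-data generator cannot satisfy the requested conditions."""
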