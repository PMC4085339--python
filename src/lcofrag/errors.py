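"""Exception hierarchy.

``LcofragError`` is the common base; the CLI maps subclasses onto its exit
codes (input/parse problems vs analysis precondition violations).
"""


class LcofragError(Exception):
    """Base class for all package errors."""


class NomenclatureError(LcofragError, ValueError):
    """A structure nomenclature string could not be parsed."""


class InvalidChemistryError(LcofragError, ValueError):
    """An elemental composition or acyl chain is chemically impossible."""


class SearchSpaceError(LcofragError, ValueError):
    """A candidate search space is empty or ill-formed."""


class PeakListError(LcofragError, ValueError):
    """A peak-list file or object is malformed."""


class AnalysisPreconditionError(LcofragError, ValueError):
    """An operation was called on inputs that violate its precondition
    (e.g. de-O-acetylating a structure that carries no O-acetyl)."""


class ConfigError(LcofragError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
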