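"""Pipeline-specific error types."""


class CsfnetError(Exception):
    """Base class for pipeline errors."""


class InvalidDesignError(CsfnetError, ValueError):
    """Cohort design is internally inconsistent (e.g. effect on an empty group)."""


class EmptyResultError(CsfnetError, ValueError):
    """An operation removed every row/sample and nothing remains to analyze."""


class ConfigurationError(CsfnetError, ValueError):
    """Stage parameters are inconsistent with the data (e.g. batch without GIS)."""


class InsufficientOverlapError(CsfnetError, ValueError):
    """Too few shared items between two tables to compute the statistic."""
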