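"""Exception hierarchy for trial validation and analysis."""


class HeatscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HeatscreenError):
    """A required column is missing or cannot be mapped."""


class IntegrityError(HeatscreenError):
    """Duplicate (cultivar, treatment, replicate, trait) rows."""


class MissingCellError(HeatscreenError):
    """A requested cultivar x treatment x trait cell has no observations."""


class MissingControlError(HeatscreenError):
    """A cultivar x trait has no control observations."""


class UnbalancedDesignError(HeatscreenError):
    """Replicate counts differ across factorial cells; ANOVA refuses.

    Carries ``cells``: the offending (cultivar, treatment, trait) keys with
    their observed replicate counts.
    """

    def __init__(self, message: str, cells=None):
        super().__init__(message)
        self.cells = list(cells or [])


class DegeneratePoolError(HeatscreenError):
    """A min-max normalisation pool has zero range: no information to scale."""


class InvalidBaselineError(HeatscreenError):
    """Control baseline is non-positive; a ratio to it is undefined."""


class ConfigError(HeatscreenError):
    """Invalid generator or pipeline configuration."""


class RankDeficiencyError(HeatscreenError):
    """Regression design matrix is not full column rank."""

    def __init__(self, message: str, terms=None):
        super().__init__(message)
        self.terms = list(terms or [])
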