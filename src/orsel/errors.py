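"""Exception hierarchy shared across the pipeline stages."""


class OrselError(Exception):
    """Base class for all pipeline errors."""


class NewickParseError(OrselError):
    """Malformed or invalid Newick input (names the offending token)."""


class UnresolvedLeafError(OrselError):
    """Gene leaves whose species id is absent from the species tree."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "gene leaves with unknown species id: " + ", ".join(map(str, self.offenders))
        )


class DegenerateLengthsError(OrselError):
    """All branch lengths in a dataset are zero; normalization is undefined."""


class UnknownBranchError(OrselError):
    """A transition member refers to a species branch absent from the assignment."""


class EmptyPopulationError(OrselError):
    """Enrichment test requested on an empty branch population."""


class DoubleCountError(OrselError):
    """Pooled tallies share members; pooling would double-count branches."""


class FormatError(OrselError):
    """External file does not follow the expected format."""


class ConfigurationError(OrselError):
    """Invalid or inconsistent analysis configuration."""


class DimensionError(OrselError):
    """Matrix dimensions disagree with the companion alignment."""


class RankError(OrselError):
    """Singular design or covariance matrix in a regression fit."""


class OptimizationError(OrselError):
    """Numerical likelihood maximization failed to produce a finite optimum."""
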