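"""Exception hierarchy shared across the package."""


class DtaBiasError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(DtaBiasError):
    """Input file is structurally unusable (missing columns, bad header)."""


class CorpusValidationError(DtaBiasError):
    """A row holds invalid values; the message names the offending row."""


class DegenerateEffectError(DtaBiasError):
    """A study effect cannot be computed (zero cell with no continuity)."""


class InsufficientDataError(DtaBiasError):
    """Too few studies / records for the requested computation."""


class NonIdentifiableError(DtaBiasError):
    """Model cannot be identified (constant outcome or predictor)."""


class IntegrityError(DtaBiasError):
    """Inconsistent intermediate results (duplicates, missing pooled effect)."""


class CatalogueError(DtaBiasError):
    """Requested funnel axis combination is not supported."""


class ScenarioError(DtaBiasError):
    """Simulation scenario is invalid or infeasible."""


class RenderError(DtaBiasError):
    """Nothing to draw."""
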