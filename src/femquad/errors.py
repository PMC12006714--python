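"""Exception and warning types shared across the package."""


class FemquadError(Exception):
    """Base class for all femquad errors."""


class FormatError(FemquadError):
    """A file or table violates the expected on-disk format."""


class IncompleteLabelingError(FormatError):
    """A required surface region is missing or empty; names the region."""

    def __init__(self, region: str, case_id: str | None = None):
        self.region = region
        self.case_id = case_id
        where = f" in case '{case_id}'" if case_id else ""
        super().__init__(f"incomplete labeling{where}: region '{region}' is missing or empty")


class DegenerateInputError(FemquadError):
    """Input data cannot support the requested fit or statistic."""


class ConvergenceError(FemquadError):
    """Iterative refinement failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class DegenerateGeometryError(FemquadError):
    """Fitted landmarks are in a degenerate configuration (e.g. collinear)."""


class AmbiguousOrientationError(FemquadError):
    """The anterior reference point does not disambiguate plane orientation."""


class UndefinedCorrelationError(FemquadError):
    """Rank correlation is undefined (a constant input vector)."""


class SpecError(FemquadError):
    """A synthetic femur or cohort specification is inconsistent."""


class RunError(FemquadError):
    """A cohort run produced no usable cases."""


class CoverageWarning(UserWarning):
    """A fitted sphere patch subtends less solid angle than recommended."""
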