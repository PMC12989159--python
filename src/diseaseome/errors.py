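"""Exception hierarchy for the diseaseome pipeline."""


class DiseaseomeError(Exception):
    """Base class for all package-specific errors."""


class GmtParseError(DiseaseomeError):
    """Raised when a GMT file is malformed (line with fewer than three
    fields, or colliding set names)."""


class ExpressionFormatError(DiseaseomeError):
    """Raised for malformed expression matrices or group files: unlabeled
    samples, non-numeric or missing cells, duplicate sample ids."""


class DegenerateDatasetError(DiseaseomeError):
    """Raised when a dataset cannot support further analysis, e.g. the
    variance filter removed every gene or a group is missing."""


class NoEligibleParametersError(DiseaseomeError):
    """Raised when no grid point satisfies the optimization constraints;
    carries the nearest-miss grid points for diagnosis."""

    def __init__(self, message: str, nearest_misses=None):
        super().__init__(message)
        self.nearest_misses = list(nearest_misses or [])
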