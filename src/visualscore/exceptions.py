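"""Exception hierarchy for the VISUAL scoring and validation pipeline."""


class VisualScoreError(Exception):
    """Base class for all package-specific errors."""


class IncompletePanelError(VisualScoreError):
    """A patient record is missing one of the five analytes needed to score."""

    def __init__(self, patient_id: str, missing: list[str]):
        self.patient_id = patient_id
        self.missing = list(missing)
        super().__init__(
            f"incomplete panel for patient {patient_id!r}: missing {', '.join(self.missing)}"
        )


class EmptyCohortError(VisualScoreError):
    """An operation received a cohort with no rows."""


class CatalogError(VisualScoreError):
    """A complication record does not match the severity catalog."""


class DegenerateClusteringError(VisualScoreError):
    """1-D two-means clustering was asked to split zero-variance data."""


class SingleClassError(VisualScoreError):
    """A classifier evaluation requires both outcome classes to be present."""


class SeparationError(VisualScoreError):
    """Logistic regression aborted: covariate completely separates the outcome."""


class CalibrationError(VisualScoreError):
    """The synthetic generator could not resolve its logistic intercept."""


class ConfigError(VisualScoreError):
    """A run configuration is invalid (bad paths, inconsistent blocks)."""
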