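"""Exception hierarchy shared across the package."""


class BrainGridError(Exception):
    """Base class for all package errors."""


class GridConfigurationError(BrainGridError):
    """Invalid plane set or planes incompatible with the template geometry."""


class OutOfBoundsError(BrainGridError):
    """A world coordinate falls outside the template bounding box."""


class EmptyInputError(BrainGridError):
    """An operation received an empty mask, map or list."""


class GeometryError(BrainGridError):
    """Volumes with incompatible shapes/affines that cannot be reconciled."""


class DegenerateSampleError(BrainGridError):
    """A statistical routine received a constant or otherwise unusable sample."""


class InvalidDesignError(BrainGridError):
    """A model cannot be estimated from the supplied design (e.g. one class only)."""


class UndefinedMetricError(BrainGridError):
    """A requested metric is undefined for the given inputs (e.g. zero denominator)."""


class CalibrationError(BrainGridError):
    """The synthetic generator could not calibrate to the requested marginals."""


class CohortValidationError(BrainGridError):
    """A cohort table violates the schema; carries the list of offending items."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("cohort validation failed: " + "; ".join(self.problems))
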