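"""Exception hierarchy for the sedcell pipeline.

Schema and configuration errors map onto distinct CLI exit codes
(2 and 3 respectively); everything else exits 1.
"""


class SedcellError(Exception):
    """Base class for all sedcell errors."""


class InvalidMeasurementError(SedcellError):
    """A cell measurement violates its physical constraints (non-positive
    or non-finite dimension, missing height for an ellipsoid, ...)."""


class InvalidShrinkageError(SedcellError):
    """Volume-shrinkage fraction outside [0, 1)."""


class InvalidInflationError(SedcellError):
    """Volume-inflation ratio below 1."""


class ConfigurationError(SedcellError):
    """Invalid configuration: unknown morphotype/modality/treatment,
    out-of-range parameter, inconsistent generator anchors."""


class InvalidCompositionError(SedcellError):
    """Amino-acid composition that cannot be normalized (all zero) or whose
    mole percentages are far from summing to 100."""


class InvalidFractionsError(SedcellError):
    """Morphotype fractions that do not sum to 1."""


class DegenerateSampleError(SedcellError):
    """A sample with no usable observations (empty, zero denominator)."""


class InvalidDesignError(SedcellError):
    """A statistical design that cannot be analyzed (too few groups or
    observations for an ANOVA)."""


class SchemaError(SedcellError):
    """An input file violating the documented column schema; carries the
    offending row/column in the message where known."""
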