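"""Exception hierarchy shared across the package."""


class AltSemError(Exception):
    """Base class for all altsem errors."""


class InputFormatError(AltSemError):
    """A file or table does not follow the documented input dialect."""


class CodingError(AltSemError):
    """A covariate column is not coded 0/1."""


class DegenerateVarianceError(AltSemError):
    """A variable has zero (or negative) variance where positive variance is required."""


class DesignError(AltSemError):
    """An analysis design is invalid (too few waves, empty cell, duplicate factor...)."""


class IdentificationError(AltSemError):
    """A model has more free parameters than sample moments."""


class StructuralError(AltSemError):
    """The path matrix defines a non-invertible (cyclic with unit product) system."""


class UnsupportedError(AltSemError):
    """The requested operation is not possible on this input type."""
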