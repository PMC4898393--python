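"""Exception hierarchy shared across the pipeline."""


class CghCnvError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CghCnvError):
    """A file does not conform to its declared format."""


class ValidationError(CghCnvError):
    """Input data violates a documented invariant."""


class DomainError(CghCnvError):
    """A value is outside the mathematical domain of an operation."""


class CapacityError(CghCnvError):
    """A placement or simulation request does not fit in the genome."""


class TrainingError(CghCnvError):
    """A model cannot be fit from the provided training data."""


class MixtureFitError(CghCnvError):
    """The read-depth mixture could not be fit on a chromosome."""
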