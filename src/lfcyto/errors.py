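"""Exception and warning types shared across the package."""


class LfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LfcError, ValueError):
    """An optical/flow/pipeline configuration violates an invariant."""


class DomainError(LfcError, ValueError):
    """An argument lies outside the physically valid domain."""


class SamplingError(LfcError, ValueError):
    """The numeric grid cannot hold the optical band limit."""


class ShapeError(LfcError, ValueError):
    """Array shapes are mutually inconsistent."""


class DataError(LfcError, ValueError):
    """Input data is malformed (NaN, negative counts, wrong dtype...)."""


class SequenceError(LfcError, ValueError):
    """A frame sequence violates an ordering/labelling contract."""


class ParameterError(LfcError, ValueError):
    """A processing parameter is invalid (e.g. non-positive radius)."""


class GeometryWarning(UserWarning):
    """The microlens geometry deviates from the 3-lenslet design."""


class PhantomWarning(UserWarning):
    """A phantom is rendered outside its guaranteed accuracy regime."""


class ClippingError(LfcError, ValueError):
    """A phantom object extends beyond the rasterization grid."""
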