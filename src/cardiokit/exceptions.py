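"""Exception hierarchy shared across the package."""


class CardiokitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiokitError):
    """Invalid bounds, hyperparameter ranges or stage configuration."""


class ShapeError(CardiokitError):
    """Mismatched array dimensions or lengths."""


class DataError(CardiokitError):
    """Invalid input data (non-finite values, missing columns, ...)."""


class DegenerateTargetError(DataError):
    """A label vector with fewer than two classes where two are required."""


class StateError(CardiokitError):
    """An object used before the required state was reached (e.g. fitness
    requested before evaluation)."""


class EvaluationError(CardiokitError):
    """An objective callback returned a non-finite value."""


class MetricError(CardiokitError):
    """A metric denominator is zero and no guard convention applies."""
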