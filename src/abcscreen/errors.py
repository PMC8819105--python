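"""Exception types raised across the pipeline."""


class AbcScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(AbcScreenError):
    """A CSV file does not match the expected column schema."""


class GridError(AbcScreenError):
    """Time grids are ragged or mismatched between series."""


class DegenerateScaleError(AbcScreenError):
    """Min-max scaling is undefined because all values are equal."""


class DenominatorError(AbcScreenError):
    """Viability denominator is non-positive (abs_vehicle <= abs_blank)."""


class ParameterError(AbcScreenError):
    """A model or generator parameter violates its constraints."""


class PlanningError(AbcScreenError):
    """Neither an IC50 nor a solubility cap is available for dose planning."""


class UndefinedEffectError(AbcScreenError):
    """Effect size is undefined (zero replicate variance or n < 2)."""
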