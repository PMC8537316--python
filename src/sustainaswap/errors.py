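"""Exception hierarchy shared across the package."""


class SustainaSwapError(Exception):
    """Base class for all package errors."""


class SchemaError(SustainaSwapError):
    """A tabular input is missing required columns or is otherwise malformed."""


class ValidationError(SustainaSwapError, ValueError):
    """A value violates a domain invariant (negative nutrient, zero weight...)."""


class FoodLookupError(SustainaSwapError, KeyError):
    """A referenced food name is not present in the food table."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError would quote the repr
        return f"food not found in table: {self.name!r}"


class ConfigurationError(SustainaSwapError):
    """A run configuration is internally inconsistent."""
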