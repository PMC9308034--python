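"""Exception types shared across the package."""


class CarenetError(Exception):
    """Base class for all carenet errors."""


class ConfigurationError(CarenetError, ValueError):
    """A configuration value is missing, malformed or out of range."""


class ValidationError(CarenetError, ValueError):
    """An input table violates the schema or referential integrity."""


class MunicipalityLookupError(CarenetError, KeyError):
    """A municipality ID has no coordinates in the gazetteer."""
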