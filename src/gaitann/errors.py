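"""Exception hierarchy for gaitann."""


class GaitannError(Exception):
    """Base class for all gaitann errors."""


class SchemaError(GaitannError):
    """A circuit file is missing a required column or has a malformed header."""


class ParseError(GaitannError):
    """A sample value could not be parsed as a number."""


class LabelError(GaitannError):
    """An activity label is not one of the seven known activities."""


class EmptyInputError(GaitannError):
    """An input file or dataset contains no rows."""


class ConfigurationError(GaitannError):
    """Inconsistent or incomplete configuration (channel sets, profiles, keys)."""
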