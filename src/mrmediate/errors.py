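"""Exception hierarchy for mrmediate."""


class MRError(Exception):
    """Base class for all mrmediate errors."""


class ConfigurationError(MRError):
    """A configuration value or required column is missing or invalid."""


class InputError(MRError):
    """An input file or table is unusable (empty, malformed)."""


class DegenerateInstrumentError(MRError):
    """An instrument has zero exposure effect; its Wald ratio is undefined."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments supplied than the method's minimum."""


class UndefinedProportionError(MRError):
    """Mediated proportion is undefined because the total effect is zero."""
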