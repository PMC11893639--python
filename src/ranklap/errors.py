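"""Exception types shared across the pipeline stages."""


class RanklapError(Exception):
    """Base class for all ranklap errors."""


class ConfigError(RanklapError):
    """A configuration problem: bad parameter value, missing column mapping."""


class InputError(RanklapError):
    """Input data violates a precondition (empty intersection, bad file)."""
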