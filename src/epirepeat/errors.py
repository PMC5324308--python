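"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (bad coordinates, empty
    sets where a statistic is undefined, out-of-range parameters)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""
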