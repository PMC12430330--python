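"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A parameter failed validation; the message names the offending field."""


class FormatError(ValueError):
    """An input file or in-memory record violates the expected layout."""
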