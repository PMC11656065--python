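"""Exception types shared across the model."""


class ConfigurationError(ValueError):
    """A model input is missing, malformed, or out of its admissible range."""


class NumericalError(RuntimeError):
    """A numerical invariant (row-stochasticity, conservation) was violated."""
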