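"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input is outside the physical domain of the model."""


class SolveError(RuntimeError):
    """A root-finding or branch-selection step failed; message carries diagnostics."""
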