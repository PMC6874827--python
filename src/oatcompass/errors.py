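"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """Input violates a documented precondition (bad alphabet, shape, range)."""


class SizingError(ValidationError):
    """A simulated chromosome is too short to host the requested features."""


class MergeConflictError(ValidationError):
    """Scaffolds claimed for one linkage group have overlapping cM spans."""
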