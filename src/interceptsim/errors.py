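"""Exception types shared across the package."""


class InvalidSpecError(ValueError):
    """A trajectory, scheme or model specification violates its invariants."""


class NoTapError(RuntimeError):
    """No tap could be detected: the finger never came close to the screen."""


class SchemaError(ValueError):
    """A trial-record file does not match the expected schema."""
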