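"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class FormatError(ValueError):
    """An on-disk cohort file violates the documented layout."""


class LeakageError(RuntimeError):
    """A sample crossed a partition boundary it must never cross.

    Raised when augmented data would enter a validation/test partition or
    when a fine-tuning sample shows up in an evaluation set.
    """
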