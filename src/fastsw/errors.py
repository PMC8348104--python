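"""Exception types shared across the package."""


class InvalidOrientationError(ValueError):
    """A quaternion cannot represent an orientation (zero or non-finite norm)."""


class NonUnitQuaternionError(ValueError):
    """An operation requiring unit quaternions received one whose norm is off by more than 1e-6."""


class TimestampOrderError(ValueError):
    """Timestamps must be strictly increasing along a signal or segment stream."""


class ExtrapolationError(ValueError):
    """A reconstruction timestamp lies outside the range covered by the segment points."""
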