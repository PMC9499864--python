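"""Exception types raised by spacetrace."""


class SpacetraceError(Exception):
    """Base class for all package errors."""


class FormatError(SpacetraceError):
    """A file does not conform to the expected dialect."""


class ValidationError(SpacetraceError):
    """Data violates a structural invariant (duplicate coordinates,
    negative intensities, inconsistent shapes, ...)."""


class AnchorError(SpacetraceError):
    """Anchor finding failed (disjoint features, zero anchors after
    filtering, ...)."""
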