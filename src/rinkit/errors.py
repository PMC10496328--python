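"""Exception hierarchy."""


class RinkitError(Exception):
    """Base class for all rinkit errors."""


class InputError(RinkitError):
    """Unreadable or malformed input."""


class EmptyStructureError(InputError):
    """A structure file yielded zero atoms."""


class EmptyIndexError(RinkitError):
    """A query requiring points was issued against an empty spatial index."""


class DegenerateRingError(RinkitError):
    """Ring plane fit attempted on collinear points."""
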