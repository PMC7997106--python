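"""Exception hierarchy for the patch-descriptor pipeline."""


class ZernipatchError(Exception):
    """Base class for all package errors."""


class ParseError(ZernipatchError):
    """A structure file could not be parsed; the message names the offending line."""


class SelectionError(ZernipatchError):
    """A residue selection is malformed or matches no atoms."""


class SurfaceError(ZernipatchError):
    """Surface construction or potential evaluation failed."""


class GridError(ZernipatchError):
    """A voxel grid violates its invariants (mass outside the unit ball, degeneracy)."""


class ConfigError(ZernipatchError):
    """A run-configuration parameter is outside its documented valid range."""
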