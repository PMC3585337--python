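"""Exception hierarchy for groovetraj."""


class GrooveTrajError(Exception):
    """Base class for all groovetraj errors."""


class ParseError(GrooveTrajError):
    """A structure or trajectory file could not be parsed."""


class FormatError(GrooveTrajError):
    """Unrecognised or unsupported file format."""


class TopologyError(GrooveTrajError):
    """Trajectory frames are inconsistent with the topology."""


class ConfigError(GrooveTrajError):
    """Invalid region map or run configuration."""


class SelectionError(GrooveTrajError):
    """An atom/residue selection resolved to nothing usable."""


class InputError(GrooveTrajError):
    """Invalid argument values (empty windows, bad ranges, ...)."""
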