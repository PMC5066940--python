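"""Exception hierarchy shared across the package."""


class DuplexLensError(Exception):
    """Base class for all package errors."""


class ParseError(DuplexLensError):
    """A coordinate file could not be parsed."""


class TopologyError(DuplexLensError):
    """Models of an ensemble do not share the same atom topology."""


class NomenclatureError(DuplexLensError):
    """A residue or atom name could not be mapped to the internal convention."""


class PairingError(DuplexLensError):
    """Two sequences are not reverse-complementary where required."""


class MissingAtomError(DuplexLensError):
    """An atom required for a geometric computation is absent."""


class FrameError(DuplexLensError):
    """A base reference frame could not be constructed."""


class CorrespondenceError(DuplexLensError):
    """Atom selections of two coordinate sets do not match one-to-one."""


class RestraintError(DuplexLensError):
    """Restraint compilation or evaluation failed."""


class BuildError(DuplexLensError):
    """The synthetic builder could not realize the requested geometry."""
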