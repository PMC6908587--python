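"""Exception hierarchy.

Every error raised by the library derives from :class:`HbstateError` so that
callers (and the CLI) can distinguish library failures from programming
errors.
"""


class HbstateError(Exception):
    """Base class for all hbstate errors."""


class ParseError(HbstateError):
    """A coordinate file could not be read."""


class FormatError(HbstateError):
    """An unknown or unsupported file format was requested."""


class InvalidOperatorError(HbstateError):
    """A rigid-body operator is not a proper rotation (det != +1)."""


class EmptySequenceError(HbstateError):
    """A chain contains no standard residues."""


class EmptyCorrespondenceError(HbstateError):
    """Residue pairing between two chains/structures produced zero pairs."""


class InsufficientPointsError(HbstateError):
    """Fewer than three point pairs were supplied to a superposition."""


class DegenerateGeometryError(HbstateError):
    """Point configuration is degenerate (e.g. collinear) for the operation."""


class UnitUnavailableError(HbstateError):
    """A structure lacks the chains required by the requested RMSD unit."""


class ClashError(HbstateError):
    """Atoms are impossibly close for a hydrogen-bond energy evaluation."""


class MalformedHemeError(HbstateError):
    """A HEM residue is missing its iron or pyrrole nitrogens."""


class NoProximalHisError(HbstateError):
    """No iron-coordinating histidine found for a heme."""


class NoDistalHisError(HbstateError):
    """No distal-histidine candidate could be identified."""


class MissingAtomError(HbstateError):
    """A required atom is absent from a residue."""


class InfeasibleSpecError(HbstateError):
    """A synthetic-geometry specification is internally inconsistent."""


class ConfigError(HbstateError):
    """An analysis configuration failed validation."""


class StageError(HbstateError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
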