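"""Exception hierarchy shared across the package.

Every error raised on a user-facing code path derives from
:class:`GpcrStateError` so callers can catch one base class.
"""


class GpcrStateError(Exception):
    """Base class for all package errors."""


class PDBFormatError(GpcrStateError):
    """A PDB record could not be parsed; the message names the line number."""


class EmptyInputError(GpcrStateError):
    """An input contained no usable coordinate records."""


class TopologyMismatchError(GpcrStateError):
    """Frames of a series do not share the topology's atom count/order."""


class LookupError_(GpcrStateError):
    """A generic-number label or residue could not be resolved."""


class PairingError(GpcrStateError):
    """Atom pairing between two structures failed for a selection."""


class GeometryError(GpcrStateError):
    """Degenerate geometry (too few points, collinear sets, zero bonds)."""


class IncompleteSideChainError(GpcrStateError):
    """A required side-chain atom is missing from a residue."""


class NoChiAngleError(GpcrStateError):
    """The residue type has no chi angle (Ala/Gly), e.g. an alanine mutant."""


class MutantDetectedError(GpcrStateError):
    """A toggle-switch position carries a side chain with no chi angles."""


class ConfigError(GpcrStateError):
    """Invalid run configuration or missing references."""
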