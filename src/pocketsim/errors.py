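"""Exception hierarchy.

Everything raised on bad data derives from :class:`PocketsimError` so the CLI
can map data problems to exit code 1 while usage errors stay with click
(exit code 2).
"""


class PocketsimError(Exception):
    """Base class for all data/processing errors."""


class PDBParseError(PocketsimError):
    """Malformed fixed-column PDB record; message names the line number."""


class EmptyStructureError(PocketsimError):
    """Parsed text contained no atoms."""


class LigandNotFoundError(PocketsimError):
    """Requested HET code absent from the structure."""


class AmbiguousLigandError(PocketsimError):
    """Requested HET code matches several groups; message lists candidates."""


class EmptySiteError(PocketsimError):
    """No residue within the pocket cutoff."""


class TooSmallSiteError(PocketsimError):
    """Fewer residues/pseudocenters than the operation needs."""


class IncompleteResidueError(PocketsimError):
    """Residue lacks atoms required for its geometric representation."""


class ClassificationError(PocketsimError):
    """Residue code outside the 20 standard amino acids."""


class EmptyProfileError(PocketsimError):
    """Every cutoff on the profile grid yielded an undefined score."""


class GenerationError(PocketsimError):
    """Synthetic pocket placement failed after bounded retries."""


class ContractViolationError(PocketsimError):
    """Caller broke a documented precondition (e.g. unsorted input)."""
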