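"""Exception hierarchy shared across the package."""


class PhyloshiftError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(PhyloshiftError):
    """Ragged alignment, empty file, or other structural alignment problem."""


class AlphabetError(AlignmentError):
    """Sequence contains a character outside the allowed alphabet."""


class TreeError(PhyloshiftError):
    """Newick parse failure or malformed tree structure."""


class DuplicateLeafError(TreeError):
    """Two leaves carry the same label."""


class PairingError(PhyloshiftError):
    """A tree and a per-node data structure do not match up."""


class DomainError(PhyloshiftError, ValueError):
    """An argument is outside its mathematical domain."""


class FitError(PhyloshiftError):
    """Nonlinear fit failed to converge after bounded restarts."""


class SelectionError(PhyloshiftError):
    """No admissible candidate during model/cluster selection."""
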