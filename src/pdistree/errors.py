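"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`PdistreeError` so the
command-line layer can map any anticipated problem to a clean nonzero exit.
"""


class PdistreeError(Exception):
    """Base class for all anticipated errors raised by this package."""


class VcfError(PdistreeError):
    """Malformed VCF input, unresolvable samples, or a bad GT field."""


class AlignmentError(PdistreeError):
    """Malformed FASTA/Phylip input or ragged alignments."""


class MatrixFormatError(PdistreeError):
    """Unreadable or inconsistent Phylip distance-matrix file."""


class MixedPloidyError(PdistreeError):
    """Two calls at one site have different ploidy and cannot be compared."""


class TreeError(PdistreeError):
    """Tree construction or consensus cannot proceed (bad matrix, leaf sets)."""


class NewickError(PdistreeError):
    """Unparseable Newick text."""


class ConfigError(PdistreeError):
    """Invalid run configuration (CLI or programmatic)."""
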