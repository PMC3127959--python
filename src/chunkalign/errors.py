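"""Exception hierarchy for chunkalign."""


class ChunkAlignError(Exception):
    """Base class for all chunkalign errors."""


class FormatError(ChunkAlignError):
    """Malformed input file (FASTA/FASTQ)."""


class ParameterError(ChunkAlignError, ValueError):
    """Invalid parameter value or combination."""


class ConsistencyError(ChunkAlignError):
    """Internal data inconsistency, e.g. a hit referencing an unknown reference."""


class RunError(ChunkAlignError):
    """A mapping run failed entirely (no chunk succeeded)."""
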