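"""Exception hierarchy shared across modules."""


class ClonephaseError(Exception):
    """Base class for analysis errors raised by this package."""


class FormatError(ClonephaseError):
    """Malformed input file (FASTA/TSV) — distinguished from analysis failures."""


class ConfigError(ClonephaseError):
    """Invalid or impossible configuration (e.g. more sites than codons)."""


class PhasingError(ClonephaseError):
    """Allele inference failed (e.g. more than two well-supported clusters)."""
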