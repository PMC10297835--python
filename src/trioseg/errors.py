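"""Exception hierarchy shared across the pipeline stages."""


class TriosegError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TriosegError):
    """A file does not conform to its declared format (FASTA/GFF3/VCF/PED/TSV)."""


class ModelError(TriosegError):
    """A transcript model violates its structural invariants."""


class ReferenceMismatchError(TriosegError):
    """A variant's REF allele disagrees with the reference genome sequence."""


class PedigreeError(TriosegError):
    """The pedigree does not support the requested operation."""


class ConfigurationError(TriosegError):
    """Missing or inconsistent run configuration (paths, accession maps...)."""


class SimulationError(TriosegError):
    """The synthetic-data generator cannot satisfy its constraints."""


class InsufficientDataError(TriosegError):
    """Too few informative observations to run a check."""


class DomainError(TriosegError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
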