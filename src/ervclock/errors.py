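"""Exception hierarchy shared across the package."""


class ErvClockError(Exception):
    """Base class for all ervclock errors."""


class FastaFormatError(ErvClockError, ValueError):
    """Malformed FASTA input (bad header, illegal residue, empty file)."""


class CoordinateError(ErvClockError, ValueError):
    """Inconsistent genomic coordinates (e.g. end < start)."""


class ConfigError(ErvClockError, ValueError):
    """Invalid simulation or run configuration."""


class InputError(ErvClockError, ValueError):
    """Invalid analysis input (empty alignment, unequal lengths, ...)."""


class UndefinedDistanceError(ErvClockError, ValueError):
    """A pairwise distance with zero usable sites after pairwise deletion."""


class SaturationError(ErvClockError, ValueError):
    """A corrected distance whose logarithm argument is non-positive."""
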