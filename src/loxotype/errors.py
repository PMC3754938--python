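"""Exception hierarchy. Each CLI-visible error class maps to a distinct exit code."""


class LoxotypeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UnsupportedSpeciesError(LoxotypeError):
    """An operation was asked for a compound class it does not support."""

    exit_code = 2


class ValidationError(LoxotypeError):
    """A record violated its schema; the message names the offending field."""

    exit_code = 3


class NormalizationError(LoxotypeError):
    """Internal-standard normalization impossible (missing or non-positive area)."""

    exit_code = 4


class TreeError(LoxotypeError):
    """Phylogeny input unusable (missing tips, unrooted without outgroup, bad Newick)."""

    exit_code = 5


class InputError(LoxotypeError):
    """Missing or empty input file, unreadable format."""

    exit_code = 6
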