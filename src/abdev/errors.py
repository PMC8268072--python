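"""Toolkit exception hierarchy.

Exit-code contract used by the CLI: config errors exit 2, data errors
exit 3, anything else (internal) exits 4.
"""


class AbdevError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(AbdevError):
    """Invalid configuration: bad boundaries, unknown keys, missing files."""

    exit_code = 2


class DataError(AbdevError):
    """Invalid input data: malformed FASTA/PDB, illegal residues."""

    exit_code = 3


class FastaParseError(DataError):
    pass


class AlphabetError(DataError):
    pass


class PdbParseError(DataError):
    pass


class StaleEditError(DataError):
    """An edit's expected source residue does not match the sequence."""
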