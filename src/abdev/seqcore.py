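"""Core sequence data model: variable-domain records, region annotation,
edit application, and variant diffing.

Positions are 1-based sequential indices per chain throughout the toolkit
(no Kabat/IMGT insertion codes); CDR boundaries come from configuration,
so literature positions must already be resolved to sequential indices.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import AlphabetError, ConfigError, DataError, FastaParseError, StaleEditError

ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
EDIT_RATIONALES = (
    "hydrophobicity",
    "ptm_removal",
    "charge_reduction",
    "germline_reversion",
    "flexibility",
    "other",
)


@dataclass(frozen=True)
class RegionMap:
    """Contiguous FR/CDR partition of a variable domain.

    ``intervals`` is an ordered tuple of ``(region_name, start, end)`` with
    1-based inclusive bounds that tile ``[1, length]`` exactly, alternating
    FR and CDR starting at FR1. Zero-length regions are dropped (a CDR
    starting at position 1 simply has no FR1 interval).
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.intervals:
            if name not in REGION_ORDER:
                raise ConfigError(f"unknown region name {name!r}")
            if start != prev_end + 1 or end < start:
                raise ConfigError(
                    f"region intervals must be contiguous and non-empty; "
                    f"got {name} [{start}, {end}] after position {prev_end}"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def region_of(self, position: int) -> str:
        """Region name at a 1-based position (binary search)."""
        if not 1 <= position <= self.length:
            raise ConfigError(f"position {position} outside [1, {self.length}]")
        starts = [iv[1] for iv in self.intervals]
        idx = bisect.bisect_right(starts, position) - 1
        return self.intervals[idx][0]

    def is_cdr(self, position: int) -> bool:
        return self.region_of(position).startswith("CDR")

    def cdr_intervals(self) -> list[tuple[str, int, int]]:
        return [iv for iv in self.intervals if iv[0].startswith("CDR")]


@dataclass(frozen=True)
class ChainRecord:
    """One variable-domain amino-acid sequence with optional region map."""

    id: str
    sequence: str
    chain_type: Optional[str] = None  # "heavy" | "light" | None
    region_map: Optional[RegionMap] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        for offset, aa in enumerate(seq):
            if aa not in ALPHABET:
                raise AlphabetError(
                    f"record {self.id!r}: illegal character {aa!r} at position {offset + 1}"
                )
        object.__setattr__(self, "sequence", seq)
        if self.chain_type not in (None, "heavy", "light"):
            raise DataError(f"record {self.id!r}: bad chain_type {self.chain_type!r}")
        if self.region_map is not None and self.region_map.length != len(seq):
            raise ConfigError(
                f"record {self.id!r}: region map covers {self.region_map.length} "
                f"positions but sequence has {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def numbering(self) -> range:
        """1-based sequential residue numbering."""
        return range(1, len(self.sequence) + 1)

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]

    def region_of(self, position: int) -> str:
        if self.region_map is None:
            return "unknown"
        return self.region_map.region_of(position)


@dataclass(frozen=True)
class Edit:
    """A point substitution on one chain, with its design rationale."""

    chain: str  # "heavy" | "light"
    position: int  # 1-based
    from_aa: str
    to_aa: str
    rationale: str = "other"

    def __post_init__(self) -> None:
        if self.chain not in ("heavy", "light"):
            raise DataError(f"edit chain must be heavy/light, got {self.chain!r}")
        if self.from_aa == self.to_aa:
            raise DataError(f"edit at {self.position}: from_aa equals to_aa ({self.from_aa})")
        if self.rationale not in EDIT_RATIONALES:
            raise ConfigError(f"unknown edit rationale {self.rationale!r}")

    @property
    def notation(self) -> str:
        """Compact ``X00Y`` notation, e.g. ``I31S``."""
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class FvPair:
    """A heavy/light variable-domain pair."""

    heavy: ChainRecord
    light: ChainRecord
    name: str = "fv"

    def __post_init__(self) -> None:
        if self.heavy.chain_type not in (None, "heavy"):
            raise DataError("heavy slot holds a non-heavy chain")
        if self.light.chain_type not in (None, "light"):
            raise DataError("light slot holds a non-light chain")

    def chain(self, which: str) -> ChainRecord:
        if which == "heavy":
            return self.heavy
        if which == "light":
            return self.light
        raise DataError(f"unknown chain {which!r}")


def read_fasta(path: str | Path) -> list[ChainRecord]:
    """Read amino-acid FASTA into ChainRecords.

    The first whitespace token of the header becomes the id; a trailing
    ``:H`` / ``:L`` tag on that token sets the chain type and is stripped.
    Sequences are upper-cased; illegal characters raise AlphabetError.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith(">"):
            break
        if stripped:
            raise FastaParseError(f"{path}:{lineno}: expected FASTA header, got {stripped[:30]!r}")
    records = []
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            token = rec.id
            chain_type = None
            if token.upper().endswith(":H"):
                chain_type, token = "heavy", token[:-2]
            elif token.upper().endswith(":L"):
                chain_type, token = "light", token[:-2]
            records.append(ChainRecord(id=token, sequence=str(rec.seq), chain_type=chain_type))
    return records


def write_fasta(records: Iterable[ChainRecord], path: str | Path) -> None:
    """Write ChainRecords as FASTA, re-attaching the ``:H``/``:L`` tag."""
    out = []
    for rec in records:
        tag = {"heavy": ":H", "light": ":L"}.get(rec.chain_type, "")
        out.append(SeqRecord(Seq(rec.sequence), id=f"{rec.id}{tag}", description=""))
    SeqIO.write(out, str(path), "fasta")


def annotate_regions(chain: ChainRecord, boundaries: dict) -> ChainRecord:
    """Attach a RegionMap built from CDR boundary config.

    ``boundaries`` maps ``cdr1``/``cdr2``/``cdr3`` to 1-based inclusive
    ``[start, end]`` pairs. Framework intervals fill the gaps.
    """
    n = len(chain)
    cdrs = []
    for key in ("cdr1", "cdr2", "cdr3"):
        if key not in boundaries:
            raise ConfigError(f"boundary config missing {key!r}")
        start, end = boundaries[key]
        if not (1 <= start <= end <= n):
            raise ConfigError(f"{key} [{start}, {end}] out of range for length {n}")
        cdrs.append((start, end))
    if not (cdrs[0][1] < cdrs[1][0] and cdrs[1][1] < cdrs[2][0]):
        raise ConfigError("CDR intervals overlap or are out of order")

    intervals: list[tuple[str, int, int]] = []
    cursor = 1
    fr_names = iter(("FR1", "FR2", "FR3", "FR4"))
    for cdr_name, (start, end) in zip(("CDR1", "CDR2", "CDR3"), cdrs):
        fr = next(fr_names)
        if cursor < start:
            intervals.append((fr, cursor, start - 1))
        intervals.append((cdr_name, start, end))
        cursor = end + 1
    if cursor <= n:
        intervals.append((next(fr_names), cursor, n))
    return replace(chain, region_map=RegionMap(tuple(intervals)))


def apply_edits(fv: FvPair, edits: list[Edit]) -> FvPair:
    """Apply point substitutions in list order, returning a new FvPair.

    Each edit's ``from_aa`` must match the *current* residue, so a later
    edit may consume an earlier product (e.g. V96S then S96P). The input
    pair is unchanged; the result name carries the edit count.
    """
    seqs = {"heavy": list(fv.heavy.sequence), "light": list(fv.light.sequence)}
    for edit in edits:
        seq = seqs[edit.chain]
        if not 1 <= edit.position <= len(seq):
            raise DataError(f"edit {edit.notation}: position outside {edit.chain} chain")
        observed = seq[edit.position - 1]
        if observed != edit.from_aa:
            raise StaleEditError(
                f"edit {edit.notation} on {edit.chain}: expected {edit.from_aa} "
                f"at position {edit.position}, found {observed}"
            )
        seq[edit.position - 1] = edit.to_aa
    heavy = replace(fv.heavy, sequence="".join(seqs["heavy"]))
    light = replace(fv.light, sequence="".join(seqs["light"]))
    return FvPair(heavy=heavy, light=light, name=f"{fv.name}+{len(edits)}edits")


def diff(parent: FvPair, variant: FvPair) -> list[Edit]:
    """Net substitutions turning parent into variant.

    One Edit per differing position, heavy chain first then light, in
    position order, with rationale ``other``. Chains must be equal length
    (the design space is substitution-only).
    """
    edits: list[Edit] = []
    for which in ("heavy", "light"):
        p, v = parent.chain(which).sequence, variant.chain(which).sequence
        if len(p) != len(v):
            raise DataError(
                f"{which} chains differ in length ({len(p)} vs {len(v)}); indels unsupported"
            )
        for i, (a, b) in enumerate(zip(p, v), start=1):
            if a != b:
                edits.append(Edit(chain=which, position=i, from_aa=a, to_aa=b))
    return edits
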