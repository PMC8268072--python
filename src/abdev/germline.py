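"""Germline comparison: global alignment, identity ranking, consensus
profiles over the most-similar V genes, and framework deviation calls.

The alignment is a Gotoh affine-gap global (Needleman-Wunsch) alignment
with deterministic tie-breaking; a gap of length L costs
``gap_open + gap_extend * L`` (positive-penalty convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigError, DataError
from .seqcore import ChainRecord

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (positive values)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def lookup(self):
        if self.matrix_name == "unit":
            # +1 match / -1 mismatch toy scheme, useful for worked examples.
            return None
        try:
            return substitution_matrices.load(self.matrix_name)
        except Exception as exc:  # pragma: no cover - depends on name
            raise ConfigError(f"unknown substitution matrix {self.matrix_name!r}") from exc

    def score(self, a: str, b: str, matrix) -> float:
        if matrix is None:
            return 1.0 if a == b else -1.0
        try:
            return float(matrix[a, b])
        except (KeyError, IndexError):
            return 0.0  # X or other non-standard symbols


@dataclass(frozen=True)
class GermlineSet:
    entries: tuple[tuple[str, str], ...]
    locus: str = "synthetic"  # IGHV | IGKV | IGLV | synthetic

    def __post_init__(self) -> None:
        if not self.entries:
            raise DataError("germline set must contain at least one entry")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.entries]


@dataclass(frozen=True)
class GermlineAlignment:
    germline_name: str
    aligned_query: str
    aligned_target: str
    identity_pct: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise DataError("aligned strings differ in length")


@dataclass(frozen=True)
class ConsensusProfile:
    """Per query position: modal germline residue among the top-k set.

    ``conservation`` is the modal residue's frequency out of k (a germline
    aligned to a gap at that position counts against conservation);
    ``unanimity`` is True iff all k germlines carry the same residue.
    """

    query_id: str
    k: int
    consensus: tuple[Optional[str], ...]
    conservation: tuple[float, ...]
    unanimity: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.consensus)


def align_global(
    query: str, target: str, scoring: ScoringScheme = ScoringScheme()
) -> GermlineAlignment:
    """Optimal global affine-gap alignment of two sequences.

    Ties in the traceback are broken deterministically: diagonal first,
    then up (gap in target), then left (gap in query).
    """
    if not query or not target:
        raise DataError("cannot align an empty sequence")
    matrix = scoring.lookup()
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(query), len(target)

    # M: query[i] aligned to target[j]; X: gap in target (up); Y: gap in query (left)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)

    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            s = scoring.score(qi, target[j - 1], matrix)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge)

    # Traceback with the stated tie preference: diagonal (M), up (X), left (Y).
    i, j = n, m
    finals = (M[i, j], X[i, j], Y[i, j])
    best = max(finals)
    state = "MXY"[finals.index(best)]
    aq, at = [], []
    while i > 0 or j > 0:
        if state == "M":
            aq.append(query[i - 1])
            at.append(target[j - 1])
            s = scoring.score(query[i - 1], target[j - 1], matrix)
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = "MXY"[prev.index(max(prev))]
            i, j = i - 1, j - 1
        elif state == "X":
            aq.append(query[i - 1])
            at.append("-")
            if i == 1 and j == 0:
                state = "M"
            else:
                cands = (M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge)
                state = "MXY"[cands.index(max(cands))]
            i -= 1
        else:
            aq.append("-")
            at.append(target[j - 1])
            if j == 1 and i == 0:
                state = "M"
            else:
                cands = (Y[i, j - 1] - ge, M[i, j - 1] - go - ge, X[i, j - 1] - go - ge)
                # preserve M > X > Y preference among equals
                ordered = (cands[1], cands[2], cands[0])
                state = "MXY"[ordered.index(max(ordered))]
            j -= 1
    aq.reverse()
    at.reverse()

    pairs = [(a, b) for a, b in zip(aq, at) if a != "-" and b != "-"]
    ident = 100.0 * sum(a == b for a, b in pairs) / len(pairs) if pairs else 0.0
    return GermlineAlignment(
        germline_name="",
        aligned_query="".join(aq),
        aligned_target="".join(at),
        identity_pct=ident,
        score=float(best),
    )


def rank_germlines(
    chain: ChainRecord, germlines: GermlineSet, scoring: ScoringScheme = ScoringScheme()
) -> list[GermlineAlignment]:
    """Align the chain to every germline; order by descending identity,
    breaking ties by score then name."""
    alignments = []
    for name, seq in germlines.entries:
        aln = align_global(chain.sequence, seq, scoring)
        alignments.append(
            GermlineAlignment(
                germline_name=name,
                aligned_query=aln.aligned_query,
                aligned_target=aln.aligned_target,
                identity_pct=aln.identity_pct,
                score=aln.score,
            )
        )
    alignments.sort(key=lambda a: (-a.identity_pct, -a.score, a.germline_name))
    return alignments


def _query_column_residues(aln: GermlineAlignment) -> list[Optional[str]]:
    """Target residue aligned to each (ungapped) query position."""
    out: list[Optional[str]] = []
    for q, t in zip(aln.aligned_query, aln.aligned_target):
        if q != "-":
            out.append(t if t != "-" else None)
    return out


def consensus_profile(
    alignments: Sequence[GermlineAlignment], query_id: str = ""
) -> ConsensusProfile:
    """Build a per-position consensus over the top-k alignments.

    All alignments must share the same query (identical ungapped query
    string). The modal residue breaks ties lexicographically.
    """
    if not alignments:
        raise ConfigError("consensus requires at least one alignment (k >= 1)")
    queries = {a.aligned_query.replace("-", "") for a in alignments}
    if len(queries) != 1:
        raise DataError("alignments do not share the same query sequence")
    k = len(alignments)
    columns = [_query_column_residues(a) for a in alignments]
    n = len(columns[0])

    consensus: list[Optional[str]] = []
    conservation: list[float] = []
    unanimity: list[bool] = []
    for pos in range(n):
        residues = [col[pos] for col in columns]
        counts = Counter(r for r in residues if r is not None)
        if not counts:
            consensus.append(None)
            conservation.append(0.0)
            unanimity.append(False)
            continue
        best_count = max(counts.values())
        # lexicographic tie-break among equally frequent residues
        modal = min(r for r, c in counts.items() if c == best_count)
        consensus.append(modal)
        conservation.append(best_count / k)
        unanimity.append(best_count == k)
    return ConsensusProfile(
        query_id=query_id,
        k=k,
        consensus=tuple(consensus),
        conservation=tuple(conservation),
        unanimity=tuple(unanimity),
    )


def deviations(
    chain: ChainRecord,
    consensus: ConsensusProfile,
    min_conservation: float = 0.7,
    include_cdr: bool = False,
) -> list[tuple[int, str, str]]:
    """Positions where the chain departs from a conserved germline consensus.

    Reports ``(position, query_residue, consensus_residue)`` where the query
    differs from the modal germline residue and the conservation fraction
    meets ``min_conservation``. Framework-only by default (all germline
    reversions of interest are framework); set ``include_cdr`` to scan CDRs.
    """
    if len(consensus) != len(chain):
        raise DataError("consensus profile length does not match chain")
    out = []
    for pos in chain.numbering:
        cons = consensus.consensus[pos - 1]
        if cons is None:
            continue
        if not include_cdr and chain.region_map is not None and chain.region_map.is_cdr(pos):
            continue
        if chain.residue(pos) != cons and consensus.conservation[pos - 1] >= min_conservation:
            out.append((pos, chain.residue(pos), cons))
    return out
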