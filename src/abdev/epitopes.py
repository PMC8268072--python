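"""HLA class II T-helper epitope scanning over 9-mer cores.

Scoring follows the pocket-profile class of class-II predictors: each
allotype is a 9 x 20 position-specific scoring matrix; a 9-mer core is a
binder for that allotype when its additive score strictly exceeds the
allotype's threshold. Cores found verbatim in human germline V genes are
whitelisted as non-immunogenic (they circulate in the natural antibody
pool). No real allotype matrices ship with the toolkit; matrices are
user-supplied TSV or synthetic test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .germline import GermlineSet
from .seqcore import ChainRecord
from ._tables import AMINO_ACIDS

CORE_LENGTH = 9
PSSM_GROUPS = ("DRB1", "DR345", "DQ", "DP")


@dataclass(frozen=True)
class AllotypePSSM:
    allotype: str
    matrix: tuple[tuple[float, ...], ...]  # 9 positions x 20 residues (AMINO_ACIDS order)
    threshold: float
    group: str = "DRB1"

    def __post_init__(self) -> None:
        if len(self.matrix) != CORE_LENGTH or any(len(row) != 20 for row in self.matrix):
            raise ConfigError(f"PSSM {self.allotype}: matrix must be 9 x 20")
        if self.group not in PSSM_GROUPS:
            raise ConfigError(f"PSSM {self.allotype}: unknown group {self.group!r}")

    def score(self, core: str) -> float:
        if len(core) != CORE_LENGTH:
            raise DataError(f"core {core!r} is not a 9-mer")
        total = 0.0
        for p, aa in enumerate(core):
            idx = AMINO_ACIDS.find(aa)
            if idx >= 0:
                total += self.matrix[p][idx]
        return total


@dataclass(frozen=True)
class EpitopeHit:
    chain: str
    start: int  # 1-based core start
    core: str
    allotypes_bound: tuple[tuple[str, float], ...]
    germline_matched: Optional[bool] = None

    @property
    def end(self) -> int:
        return self.start + CORE_LENGTH - 1


@dataclass(frozen=True)
class EpitopeCluster:
    start: int
    end: int
    hits: tuple[EpitopeHit, ...]
    breadth: int  # distinct allotypes across member hits


def scan_epitopes(chain: ChainRecord, pssms: Sequence[AllotypePSSM]) -> list[EpitopeHit]:
    """Score every 9-mer against every matrix; one hit per binding core.

    A sequence shorter than nine residues yields no hits. Binding is
    strict: score must exceed the threshold.
    """
    seq = chain.sequence
    chain_name = chain.chain_type or "unknown"
    hits = []
    for start in range(len(seq) - CORE_LENGTH + 1):
        core = seq[start : start + CORE_LENGTH]
        bound = tuple(
            (p.allotype, p.score(core)) for p in pssms if p.score(core) > p.threshold
        )
        if bound:
            hits.append(
                EpitopeHit(chain=chain_name, start=start + 1, core=core, allotypes_bound=bound)
            )
    return hits


def germline_filter(
    hits: Sequence[EpitopeHit], germlines: GermlineSet
) -> tuple[list[EpitopeHit], list[EpitopeHit]]:
    """Whitelist germline-encoded cores.

    Returns ``(annotated, filtered)``: every hit annotated with whether its
    core occurs verbatim in any germline entry, and the sub-list of
    non-germline hits. Idempotent and never hit-increasing.
    """
    annotated = []
    for hit in hits:
        matched = any(hit.core in seq for seq in germlines.sequences)
        annotated.append(replace(hit, germline_matched=matched))
    filtered = [h for h in annotated if not h.germline_matched]
    return annotated, filtered


def cluster(hits: Sequence[EpitopeHit]) -> list[EpitopeCluster]:
    """Single-linkage merge of hits whose cores share at least one residue."""
    ordered = sorted(hits, key=lambda h: h.start)
    clusters: list[EpitopeCluster] = []
    group: list[EpitopeHit] = []
    for hit in ordered:
        if group and hit.start <= group[-1].end:  # cores overlap
            group.append(hit)
        else:
            if group:
                clusters.append(_finish(group))
            group = [hit]
    if group:
        clusters.append(_finish(group))
    return clusters


def _finish(group: list[EpitopeHit]) -> EpitopeCluster:
    allotypes = {a for h in group for a, _ in h.allotypes_bound}
    return EpitopeCluster(
        start=group[0].start,
        end=max(h.end for h in group),
        hits=tuple(group),
        breadth=len(allotypes),
    )


def filtered_clusters(
    chain: ChainRecord, pssms: Sequence[AllotypePSSM], germlines: Optional[GermlineSet]
) -> list[EpitopeCluster]:
    """Scan, germline-filter, and cluster in one step."""
    hits = scan_epitopes(chain, pssms)
    if germlines is not None:
        _, hits = germline_filter(hits, germlines)
    return cluster(hits)


def epitope_delta(
    parent_chain: ChainRecord,
    variant_chain: ChainRecord,
    pssms: Sequence[AllotypePSSM],
    germlines: Optional[GermlineSet] = None,
) -> tuple[list[EpitopeCluster], list[EpitopeCluster], int]:
    """Compare germline-filtered cluster sets of two equal-length chains.

    Returns ``(removed, created, net_breadth_change)``; clusters are keyed
    by their (start, end) span. Any created cluster marks the variant as
    immunogenicity-increasing.
    """
    if len(parent_chain) != len(variant_chain):
        raise DataError("epitope_delta requires equal-length chains")
    parent = {(c.start, c.end): c for c in filtered_clusters(parent_chain, pssms, germlines)}
    variant = {(c.start, c.end): c for c in filtered_clusters(variant_chain, pssms, germlines)}
    removed = [c for k, c in parent.items() if k not in variant]
    created = [c for k, c in variant.items() if k not in parent]
    net_breadth = sum(c.breadth for c in variant.values()) - sum(
        c.breadth for c in parent.values()
    )
    return removed, created, net_breadth


def read_pssms(path: str | Path) -> list[AllotypePSSM]:
    """Load PSSMs from TSV: one row per (allotype, position) with the 20
    residue columns plus per-allotype threshold and group."""
    df = pd.read_csv(path, sep="\t")
    required = {"allotype", "position", "threshold"} | set(AMINO_ACIDS)
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"PSSM TSV missing columns {sorted(missing)}")
    out = []
    for allotype, sub in df.groupby("allotype", sort=True):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(1, CORE_LENGTH + 1)):
            raise ConfigError(f"PSSM {allotype}: positions must be exactly 1..9")
        matrix = tuple(
            tuple(float(row[aa]) for aa in AMINO_ACIDS) for _, row in sub.iterrows()
        )
        thresholds = set(sub["threshold"])
        if len(thresholds) != 1:
            raise ConfigError(f"PSSM {allotype}: inconsistent thresholds")
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else "DRB1"
        out.append(
            AllotypePSSM(
                allotype=str(allotype),
                matrix=matrix,
                threshold=float(thresholds.pop()),
                group=group,
            )
        )
    return out


def write_pssms(pssms: Sequence[AllotypePSSM], path: str | Path) -> None:
    rows = []
    for p in pssms:
        for pos in range(CORE_LENGTH):
            row = {"allotype": p.allotype, "position": pos + 1,
                   "threshold": p.threshold, "group": p.group}
            row.update({aa: p.matrix[pos][i] for i, aa in enumerate(AMINO_ACIDS)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
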