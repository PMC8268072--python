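"""Rule-based PTM liability motif scanning with solvent-exposure gating.

Liability classes covered: Asn deamidation, Asp isomerization,
N-glycosylation (N-X-S/T sequon, X != P), O-glycosylation (weak S/T-run
heuristic), Met/Trp oxidation, and unpaired cysteines. Follower sets are
configuration, not hard-coded chemistry: the defaults below follow the
degradation literature (NG/NS/NT/NA deamidation; DG/DS/DD/DT
isomerization) and can be overridden per run.

Pattern mini-syntax (per rule):
  - ``M``            a single anchor residue
  - ``N[GSTA]``      anchor followed by one residue from the class
  - ``N[^P][ST]``    token sequence; ``[^P]`` is a complement class
  - ``run:ST:3``     a homogeneous run of residues from the class, length >= 3
The anchor position reported for a hit is the first token's position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

from .errors import ConfigError, DataError
from .seqcore import ChainRecord

LIABILITY_TYPES = (
    "deamidation",
    "isomerization",
    "n_glycosylation",
    "o_glycosylation",
    "oxidation",
    "unpaired_cysteine",
)

_TOKEN_RE = re.compile(r"\[\^?[A-Z]+\]|[A-Z]")


@dataclass(frozen=True)
class LiabilityRule:
    liability_type: str
    pattern: str
    severity: str = "medium"  # base severity; CDR anchors escalate to high

    def __post_init__(self) -> None:
        if self.liability_type not in LIABILITY_TYPES:
            raise ConfigError(f"unknown liability type {self.liability_type!r}")
        if not self.pattern:
            raise ConfigError("empty liability pattern")
        if self.severity not in ("high", "medium", "low"):
            raise ConfigError(f"bad severity {self.severity!r}")


@dataclass(frozen=True)
class LiabilityHit:
    chain: str
    position: int  # 1-based anchor
    liability_type: str
    motif: str
    region: str = "unknown"
    exposed: Optional[bool] = None
    severity: str = "medium"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.position, self.liability_type)


def default_rules() -> list[LiabilityRule]:
    """The stock rule set.

    Canonical (paired) cysteine positions are whitelisted at scan time via
    ``scan_motifs(..., allowed_cys=...)``; any C elsewhere is flagged.
    """
    return [
        LiabilityRule("deamidation", "N[GSTA]"),
        LiabilityRule("isomerization", "D[GSDT]"),
        LiabilityRule("n_glycosylation", "N[^P][ST]"),
        LiabilityRule("o_glycosylation", "run:ST:3", severity="low"),
        LiabilityRule("oxidation", "M"),
        LiabilityRule("oxidation", "W"),
        LiabilityRule("unpaired_cysteine", "C"),
    ]


def _compile_tokens(pattern: str) -> list[tuple[frozenset, bool]]:
    """Compile a token pattern into (residue_set, complement?) tuples."""
    tokens = _TOKEN_RE.findall(pattern)
    if "".join(tokens) != pattern:
        raise ConfigError(f"unparseable liability pattern {pattern!r}")
    out = []
    for tok in tokens:
        if tok.startswith("[^"):
            out.append((frozenset(tok[2:-1]), True))
        elif tok.startswith("["):
            out.append((frozenset(tok[1:-1]), False))
        else:
            out.append((frozenset(tok), False))
    return out


def _match_at(seq: str, i: int, tokens) -> Optional[str]:
    if i + len(tokens) > len(seq):
        return None
    for offset, (allowed, complement) in enumerate(tokens):
        aa = seq[i + offset]
        inside = aa in allowed
        if inside == complement:
            return None
    return seq[i : i + len(tokens)]


def scan_motifs(
    chain: ChainRecord,
    rules: Optional[Sequence[LiabilityRule]] = None,
    allowed_cys: Sequence[int] = (),
) -> list[LiabilityHit]:
    """Report every rule occurrence on the chain, sorted by position.

    Overlapping motifs are all reported and a single anchor may produce
    hits of several types (e.g. NGT is both a deamidation and a sequon).
    Region labels come from the chain's RegionMap when present; regions
    never filter hits, they only label them.
    """
    if rules is None:
        rules = default_rules()
    seq = chain.sequence
    chain_name = chain.chain_type or "unknown"
    allowed = set(allowed_cys)
    hits: list[LiabilityHit] = []
    for rule in rules:
        if rule.pattern.startswith("run:"):
            try:
                _, klass, min_len_s = rule.pattern.split(":")
                min_len = int(min_len_s)
            except ValueError as exc:
                raise ConfigError(f"bad run pattern {rule.pattern!r}") from exc
            run_re = re.compile(f"[{klass}]{{{min_len},}}")
            for m in run_re.finditer(seq):
                hits.append(
                    _make_hit(chain, chain_name, m.start() + 1, rule, m.group())
                )
            continue
        tokens = _compile_tokens(rule.pattern)
        for i in range(len(seq)):
            motif = _match_at(seq, i, tokens)
            if motif is None:
                continue
            pos = i + 1
            if rule.liability_type == "unpaired_cysteine" and pos in allowed:
                continue
            hits.append(_make_hit(chain, chain_name, pos, rule, motif))
    hits.sort(key=lambda h: (h.position, LIABILITY_TYPES.index(h.liability_type)))
    return hits


def _make_hit(chain: ChainRecord, chain_name: str, pos: int, rule: LiabilityRule, motif: str):
    region = chain.region_of(pos)
    if rule.severity == "low":
        severity = "low"
    elif region.startswith("CDR"):
        severity = "high"
    else:
        severity = rule.severity
    return LiabilityHit(
        chain=chain_name,
        position=pos,
        liability_type=rule.liability_type,
        motif=motif,
        region=region,
        severity=severity,
    )


def gate_by_exposure(
    hits: Sequence[LiabilityHit],
    exposure: Union["ExposureProfile", Mapping[str, "ExposureProfile"]],
    threshold: float = 0.5,
    demote_buried: bool = True,
) -> list[LiabilityHit]:
    """Annotate hits with solvent exposure at the anchor.

    A hit is ``exposed`` when relative exposure at its anchor meets the
    threshold. Buried hits are demoted to severity ``low`` (never deleted):
    a buried Asn still deamidates, just more slowly.
    """
    out = []
    for hit in hits:
        prof = exposure[hit.chain] if isinstance(exposure, Mapping) else exposure
        if hit.position > len(prof.relative):
            raise DataError(f"exposure profile missing position {hit.position}")
        rel = prof.relative[hit.position - 1]
        exposed = rel >= threshold
        severity = hit.severity
        if demote_buried and not exposed:
            severity = "low"
        out.append(replace(hit, exposed=exposed, severity=severity))
    return out


def liability_delta(
    parent_hits: Sequence[LiabilityHit],
    variant_hits: Sequence[LiabilityHit],
    parent_rules: Optional[Sequence[LiabilityRule]] = None,
    variant_rules: Optional[Sequence[LiabilityRule]] = None,
) -> tuple[list[LiabilityHit], list[LiabilityHit], list[LiabilityHit]]:
    """(removed, created, unchanged) keyed on (chain, position, type).

    Both hit lists must come from the same rule set; pass the rule sets to
    have that checked.
    """
    if parent_rules is not None and variant_rules is not None:
        if list(parent_rules) != list(variant_rules):
            raise ConfigError("liability_delta: hit lists computed with different rule sets")
    parent_keys = {h.key: h for h in parent_hits}
    variant_keys = {h.key: h for h in variant_hits}
    removed = [h for k, h in parent_keys.items() if k not in variant_keys]
    created = [h for k, h in variant_keys.items() if k not in parent_keys]
    unchanged = [h for k, h in parent_keys.items() if k in variant_keys]
    return removed, created, unchanged
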