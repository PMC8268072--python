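"""Variant design: position criticality, rule-based substitution proposal,
constraint filtering, and multi-criteria ranking.

The proposal rules mirror the five design-move families used in antibody
developability optimisation:

  a. hydrophobicity — exposed aliphatic/aromatic CDR residues to Ser/Thr
     (surface-hydrophobicity reduction);
  b. ptm_removal    — liability anchors or followers substituted to break
     the motif (N->Q, D->E, follower G/S->A);
  c. charge_reduction — exposed framework Lys/Arg off-consensus positions
     reverted to the germline consensus residue (lowers pI);
  d. germline_reversion — framework deviations at unanimously conserved
     germline positions reverted;
  e. flexibility    — a Pro introduced at the canonical penultimate
     position of a long, Gly-rich CDR-L3 to rigidify the loop.

Candidates are filtered so that no admissible edit touches a Critical
position (outside the explicit CDR allowances), creates a liability or an
epitope cluster, or raises the intrinsic aggregation total. Ranking is a
deterministic lexicographic order putting immunogenicity safety first,
then PTM load, then surface and intrinsic aggregation, then germline
identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .biophys import (
    AggregationProfile,
    ChargeModel,
    PropensityScales,
    aggregation_profile,
    isoelectric_point,
)
from .epitopes import AllotypePSSM, filtered_clusters
from .errors import ConfigError, DataError
from .germline import (
    ConsensusProfile,
    GermlineSet,
    ScoringScheme,
    consensus_profile,
    deviations,
    rank_germlines,
)
from .liabilities import LiabilityHit, LiabilityRule, default_rules, gate_by_exposure, scan_motifs
from .seqcore import ChainRecord, Edit, FvPair, apply_edits
from .structure import ExposureProfile, default_exposure

HYDROPHOBIC = frozenset("ILVFMW")
POSITION_CLASSES = ("Neutral", "Contributing", "Critical")


@dataclass(frozen=True)
class DesignConfig:
    """Knobs governing classification, proposal, and filtering."""

    buried_threshold: float = 0.25  # relative exposure below which a position is buried
    exposed_threshold: float = 0.5  # exposure at or above which a residue is "surface"
    min_conservation: float = 0.7
    top_k_germlines: int = 5
    interface_positions: Mapping[str, Sequence[int]] = field(default_factory=dict)
    allow_cdr_edits: bool = True
    # families permitted to touch CDR positions
    cdr_allowed_families: tuple[str, ...] = ("hydrophobicity", "ptm_removal", "flexibility")
    a_tot_tolerance: float = 0.0
    max_combination: int = 6
    # canonical Pro position within CDR-L3, counted from the loop end
    # (2 = penultimate)
    l3_pro_offset: int = 2
    allowed_cys: Mapping[str, Sequence[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class PositionClass:
    """Per-position risk classes for one Fv (keyed (chain, position))."""

    classes: Mapping[tuple[str, int], str]
    rationales: Mapping[tuple[str, int], tuple[str, ...]]

    def of(self, chain: str, position: int) -> str:
        return self.classes[(chain, position)]

    def codes(self, chain: str, position: int) -> tuple[str, ...]:
        return self.rationales[(chain, position)]


@dataclass(frozen=True)
class CandidateEdit:
    edit: Edit
    expected_effects: Mapping[str, float]

    @property
    def notation(self) -> str:
        return f"{self.edit.chain[0].upper()}:{self.edit.notation}"


@dataclass(frozen=True)
class VariantReport:
    name: str
    edits: tuple[Edit, ...]
    metrics: Mapping[str, float]
    deltas: Mapping[str, float]
    constraints: Mapping[str, bool]
    rank: int = 0


@dataclass(frozen=True)
class ChainMetrics:
    a_tot: float
    t_tot: float
    liability_keys: frozenset
    epitope_spans: frozenset
    top_identity: float
    agg: AggregationProfile
    hits: tuple[LiabilityHit, ...]


@dataclass
class FvContext:
    """Everything the design operations need about one Fv."""

    fv: FvPair
    germline_sets: Mapping[str, GermlineSet]
    pssms: Sequence[AllotypePSSM] = ()
    exposure: Mapping[str, ExposureProfile] = field(default_factory=dict)
    rules: Sequence[LiabilityRule] = field(default_factory=default_rules)
    scales: PropensityScales = field(default_factory=PropensityScales)
    charge_model: ChargeModel = field(default_factory=ChargeModel)
    config: DesignConfig = field(default_factory=DesignConfig)
    consensus: dict = field(default_factory=dict)
    chain_metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for which in ("heavy", "light"):
            chain = self.fv.chain(which)
            if which not in self.exposure:
                self.exposure = {**self.exposure, which: default_exposure(len(chain), which)}
            ranked = rank_germlines(chain, self.germline_sets[which])
            top = ranked[: self.config.top_k_germlines]
            self.consensus[which] = consensus_profile(top, query_id=chain.id)
            self.chain_metrics[which] = self._metrics(chain, which, ranked)

    def _metrics(self, chain: ChainRecord, which: str, ranked) -> ChainMetrics:
        hits = scan_motifs(
            chain, self.rules, allowed_cys=self.config.allowed_cys.get(which, ())
        )
        hits = gate_by_exposure(hits, self.exposure[which])
        agg = aggregation_profile(
            chain.sequence, exposure=self.exposure[which], scales=self.scales
        )
        clusters = filtered_clusters(chain, self.pssms, self.germline_sets[which])
        return ChainMetrics(
            a_tot=agg.A_tot,
            t_tot=agg.T_tot if agg.T_tot is not None else 0.0,
            liability_keys=frozenset(h.key for h in hits),
            epitope_spans=frozenset((c.start, c.end) for c in clusters),
            top_identity=ranked[0].identity_pct if ranked else 0.0,
            agg=agg,
            hits=tuple(hits),
        )

    def chain_metrics_for(self, chain: ChainRecord, which: str) -> ChainMetrics:
        """Metrics for an edited version of one chain (exposure reused:
        a point substitution is assumed not to refold the domain)."""
        ranked = rank_germlines(chain, self.germline_sets[which])
        return self._metrics(chain, which, ranked)

    def summary(self) -> dict[str, float]:
        return summarize(self.fv, self.chain_metrics, self.charge_model)


def summarize(fv: FvPair, per_chain: Mapping[str, ChainMetrics], charge_model: ChargeModel):
    """Whole-Fv scalar metrics used for candidate effects and ranking."""
    heavy, light = per_chain["heavy"], per_chain["light"]
    return {
        "A_tot": heavy.a_tot + light.a_tot,
        "T_tot": heavy.t_tot + light.t_tot,
        "liability_count": len(heavy.liability_keys) + len(light.liability_keys),
        "epitope_clusters": len(heavy.epitope_spans) + len(light.epitope_spans),
        "pI": isoelectric_point([fv.heavy.sequence, fv.light.sequence], charge_model),
        "germline_identity": 0.5 * (heavy.top_identity + light.top_identity),
    }


def classify_positions(context: FvContext) -> PositionClass:
    """Assign Neutral / Contributing / Critical to every Fv position.

    Critical: CDR positions, configured interface positions, and buried
    positions that are unanimously conserved in the germline set.
    Contributing: buried positions (packing) and positions within two
    residues of a CDR boundary. Everything else is Neutral.
    """
    classes: dict[tuple[str, int], str] = {}
    rationales: dict[tuple[str, int], tuple[str, ...]] = {}
    cfg = context.config
    for which in ("heavy", "light"):
        chain = context.fv.chain(which)
        if chain.region_map is None:
            raise DataError(f"{which} chain lacks region annotation")
        exposure = context.exposure[which].relative
        cons = context.consensus[which]
        interface = set(cfg.interface_positions.get(which, ()))
        cdr_edges: set[int] = set()
        for _, start, end in chain.region_map.cdr_intervals():
            for d in (1, 2):
                cdr_edges.update({start - d, end + d})
        for pos in chain.numbering:
            codes = []
            buried = exposure[pos - 1] < cfg.buried_threshold
            if chain.region_map.is_cdr(pos):
                codes.append("cdr")
            if pos in interface:
                codes.append("interface")
            if buried and cons.unanimity[pos - 1]:
                codes.append("germline_invariant")
            if codes:
                cls = "Critical"
            else:
                if buried:
                    codes.append("buried_packing")
                if pos in cdr_edges:
                    codes.append("vernier_config")
                cls = "Contributing" if codes else "Neutral"
            classes[(which, pos)] = cls
            rationales[(which, pos)] = tuple(codes)
    return PositionClass(classes=classes, rationales=rationales)


def _candidate(context: FvContext, edit: Edit) -> CandidateEdit:
    """Attach recomputed whole-Fv effect deltas to a proposed edit."""
    parent = context.summary()
    chain = context.fv.chain(edit.chain)
    edited = apply_edits(context.fv, [edit]).chain(edit.chain)
    edited = replace(edited, region_map=chain.region_map)
    new_metrics = dict(context.chain_metrics)
    new_metrics[edit.chain] = context.chain_metrics_for(edited, edit.chain)
    new_fv = FvPair(
        heavy=edited if edit.chain == "heavy" else context.fv.heavy,
        light=edited if edit.chain == "light" else context.fv.light,
        name=context.fv.name,
    )
    var = summarize(new_fv, new_metrics, context.charge_model)
    old_keys = context.chain_metrics[edit.chain].liability_keys
    new_keys = new_metrics[edit.chain].liability_keys
    old_spans = context.chain_metrics[edit.chain].epitope_spans
    new_spans = new_metrics[edit.chain].epitope_spans
    effects = {
        "dA_tot": var["A_tot"] - parent["A_tot"],
        "dT_tot": var["T_tot"] - parent["T_tot"],
        "dliability_count": var["liability_count"] - parent["liability_count"],
        "liabilities_created": len(new_keys - old_keys),
        "depitope_clusters": var["epitope_clusters"] - parent["epitope_clusters"],
        "epitope_clusters_created": len(new_spans - old_spans),
        "dpI": var["pI"] - parent["pI"],
        "dgermline_identity": var["germline_identity"] - parent["germline_identity"],
    }
    return CandidateEdit(edit=edit, expected_effects=effects)


def propose(context: FvContext) -> list[CandidateEdit]:
    """Emit candidate edits for every design family that triggers."""
    cfg = context.config
    edits: list[Edit] = []
    for which in ("heavy", "light"):
        chain = context.fv.chain(which)
        if chain.region_map is None:
            raise DataError(f"{which} chain lacks region annotation")
        exposure = context.exposure[which].relative
        cons = context.consensus[which]
        metrics = context.chain_metrics[which]

        # (a) surface hydrophobicity: exposed aliphatic/aromatic CDR residues
        for pos in chain.numbering:
            aa = chain.residue(pos)
            if (
                chain.region_map.is_cdr(pos)
                and aa in HYDROPHOBIC
                and exposure[pos - 1] >= cfg.exposed_threshold
            ):
                for target in ("S", "T"):
                    edits.append(Edit(which, pos, aa, target, "hydrophobicity"))

        # (b) PTM removal at liability anchors / followers
        for hit in metrics.hits:
            anchor = hit.position
            aa = chain.residue(anchor)
            if hit.liability_type in ("deamidation", "n_glycosylation") and aa == "N":
                edits.append(Edit(which, anchor, "N", "Q", "ptm_removal"))
            if hit.liability_type == "isomerization" and aa == "D":
                edits.append(Edit(which, anchor, "D", "E", "ptm_removal"))
            if hit.liability_type in ("deamidation", "isomerization") and anchor < len(chain):
                follower = chain.residue(anchor + 1)
                if follower in "GS":
                    edits.append(Edit(which, anchor + 1, follower, "A", "ptm_removal"))

        # (c) charge reduction: exposed framework K/R off consensus
        devs = deviations(chain, cons, min_conservation=cfg.min_conservation)
        for pos, query_aa, cons_aa in devs:
            if query_aa in "KR" and exposure[pos - 1] >= cfg.exposed_threshold:
                if cons_aa not in "KR" and cons_aa != query_aa:
                    edits.append(Edit(which, pos, query_aa, cons_aa, "charge_reduction"))

        # (d) germline reversion at unanimity positions
        for pos, query_aa, cons_aa in devs:
            if cons.unanimity[pos - 1]:
                edits.append(Edit(which, pos, query_aa, cons_aa, "germline_reversion"))

        # (e) CDR-L3 rigidification: introduce the canonical penultimate Pro
        if which == "light":
            for name, start, end in chain.region_map.cdr_intervals():
                if name != "CDR3":
                    continue
                loop = chain.sequence[start - 1 : end]
                pro_pos = end - cfg.l3_pro_offset + 1
                if (
                    loop.count("G") >= 2
                    and "P" not in loop
                    and start <= pro_pos <= end
                    and chain.residue(pro_pos) != "P"
                ):
                    edits.append(
                        Edit(which, pro_pos, chain.residue(pro_pos), "P", "flexibility")
                    )

    # drop duplicates, keep first occurrence (family order above)
    seen = set()
    unique = []
    for e in edits:
        key = (e.chain, e.position, e.to_aa)
        if key not in seen:
            seen.add(key)
            unique.append(e)
    return [_candidate(context, e) for e in unique]


def filter_candidates(
    candidates: Sequence[CandidateEdit],
    context: FvContext,
    classes: PositionClass,
) -> list[CandidateEdit]:
    """Keep only admissible candidates.

    Rejected: edits at Critical positions (unless the position is Critical
    solely for being in a CDR and the family carries a CDR allowance),
    edits creating any liability or epitope cluster, and edits raising
    A_tot beyond the configured tolerance.
    """
    cfg = context.config
    out = []
    for cand in candidates:
        e = cand.edit
        cls = classes.of(e.chain, e.position)
        codes = set(classes.codes(e.chain, e.position))
        if cls == "Critical":
            cdr_only = codes == {"cdr"}
            allowed = (
                cfg.allow_cdr_edits
                and cdr_only
                and e.rationale in cfg.cdr_allowed_families
            )
            if not allowed:
                continue
        eff = cand.expected_effects
        if eff["liabilities_created"] > 0:
            continue
        if eff["epitope_clusters_created"] > 0:
            continue
        if eff["dA_tot"] > cfg.a_tot_tolerance:
            continue
        out.append(cand)
    return out


def assemble_variants(
    parent: FvPair,
    admissible: Sequence[CandidateEdit],
    max_combination: int = 6,
    top_k: int = 10,
) -> list[tuple[str, FvPair, tuple[Edit, ...]]]:
    """Build variant Fvs: the ``top_k`` single admissible edits (largest
    surface-aggregation reduction first), plus one combined variant drawn
    round-robin from the design families (at most ``max_combination``
    edits, one per position)."""
    singles = sorted(
        admissible,
        key=lambda c: (c.expected_effects["dT_tot"], c.expected_effects["dA_tot"], c.notation),
    )[:top_k]
    variants = []
    for cand in singles:
        fv = apply_edits(parent, [cand.edit])
        fv = FvPair(heavy=_keep_regions(parent.heavy, fv.heavy),
                    light=_keep_regions(parent.light, fv.light),
                    name=f"{parent.name}_{cand.notation}")
        variants.append((fv.name, fv, (cand.edit,)))
    # combined variant: round-robin across design families so the multi-edit
    # lead addresses every defect class, not six variations of one
    families = ("hydrophobicity", "ptm_removal", "charge_reduction",
                "germline_reversion", "flexibility", "other")
    queues = {f: [c for c in admissible if c.edit.rationale == f] for f in families}
    combo: list[Edit] = []
    taken: set[tuple[str, int]] = set()
    progressed = True
    while len(combo) < max_combination and progressed:
        progressed = False
        for family in families:
            while queues[family]:
                cand = queues[family].pop(0)
                key = (cand.edit.chain, cand.edit.position)
                if key in taken:
                    continue
                taken.add(key)
                combo.append(cand.edit)
                progressed = True
                break
            if len(combo) >= max_combination:
                break
    if len(combo) > 1:
        fv = apply_edits(parent, combo)
        fv = FvPair(heavy=_keep_regions(parent.heavy, fv.heavy),
                    light=_keep_regions(parent.light, fv.light),
                    name=f"{parent.name}_combo{len(combo)}")
        variants.append((fv.name, fv, tuple(combo)))
    return variants


def _keep_regions(template: ChainRecord, chain: ChainRecord) -> ChainRecord:
    return replace(chain, region_map=template.region_map)


def rank_variants(
    variants: Sequence[FvPair],
    parent_context: FvContext,
    names: Optional[Sequence[str]] = None,
    edit_lists: Optional[Sequence[tuple[Edit, ...]]] = None,
) -> list[VariantReport]:
    """Deterministic total order over variants.

    Ascending on (epitope clusters created vs parent, liability count,
    T_tot, A_tot), then descending germline identity, then name.
    """
    if not variants:
        raise DataError("rank_variants requires at least one variant")
    names = list(names) if names is not None else [v.name for v in variants]
    edit_lists = list(edit_lists) if edit_lists is not None else [()] * len(variants)
    parent = parent_context.summary()
    parent_spans = {
        which: parent_context.chain_metrics[which].epitope_spans
        for which in ("heavy", "light")
    }
    reports = []
    for name, fv, edits in zip(names, variants, edit_lists):
        per_chain = {}
        created = 0
        for which in ("heavy", "light"):
            chain = _keep_regions(parent_context.fv.chain(which), fv.chain(which))
            per_chain[which] = parent_context.chain_metrics_for(chain, which)
            created += len(per_chain[which].epitope_spans - parent_spans[which])
        m = summarize(fv, per_chain, parent_context.charge_model)
        m["epitope_clusters_created"] = created
        deltas = {f"d{k}": m[k] - parent[k] for k in parent}
        constraints = {
            "no_new_epitope_clusters": created == 0,
            "no_new_liabilities": m["liability_count"] <= parent["liability_count"],
            "a_tot_not_increased": m["A_tot"]
            <= parent["A_tot"] + parent_context.config.a_tot_tolerance,
        }
        reports.append(
            VariantReport(name=name, edits=tuple(edits), metrics=m, deltas=deltas,
                          constraints=constraints)
        )
    reports.sort(
        key=lambda r: (
            r.metrics["epitope_clusters_created"],
            r.metrics["liability_count"],
            r.metrics["T_tot"],
            r.metrics["A_tot"],
            -r.metrics["germline_identity"],
            r.name,
        )
    )
    return [replace(r, rank=i + 1) for i, r in enumerate(reports)]
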