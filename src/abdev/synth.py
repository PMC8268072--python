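"""Seeded synthetic test bed: germline sets, antibody-like Fv pairs with
planted liability motifs / deviations / epitope cores, toy structures,
and synthetic HLA-II scoring matrices.

Every generator is deterministic per seed (NumPy Generator with explicit
integer seeding). Fixtures carry a ground-truth ledger so detector tests
can assert exact recovery: the generator *verifies* that each planted
feature is the only thing its detector will find (resampling residues at
accidental motif anchors, then redrawing wholesale within a bounded retry
budget) rather than trying to prove cleanliness constructively.

The emulated landscape mirrors a germline-derived variable domain carrying
the classic developability defects: PTM motifs in the CDRs, an exposed
hydrophobic CDR patch, surplus framework Lys/Arg off the germline
consensus, a framework residue departing from a unanimous germline
consensus, and a non-germline HLA-II binder core. None of this is a
biophysically realistic antibody; it is a controlled substrate for
detector and design-rule testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.SeqUtils import seq3

from .errors import ConfigError, DataError
from .germline import GermlineSet, consensus_profile, deviations, rank_germlines
from .liabilities import scan_motifs
from .seqcore import ChainRecord, FvPair, annotate_regions
from .structure import Atom, StructureModel
from .epitopes import AllotypePSSM, CORE_LENGTH
from ._tables import AMINO_ACIDS

# Residues that can never seed or extend a default liability motif:
# excludes anchors (N, D, M, W, C) and the S/T follower/run residues.
SAFE_ALPHABET = "AEFGHIKLPQRVY"

DEFAULT_BOUNDARIES = {
    "heavy": {"cdr1": (26, 33), "cdr2": (51, 58), "cdr3": (93, 104)},
    "light": {"cdr1": (24, 34), "cdr2": (50, 56), "cdr3": (89, 98)},
}


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_germlines: int = 8
    domain_length: int = 110
    mutation_rate: float = 0.05
    top_k: int = 5
    min_conservation: float = 0.7
    max_retries: int = 20


@dataclass(frozen=True)
class PlantSpec:
    """What to plant into a clean Fv background.

    Liability, hydrophobic-patch and epitope plants must sit inside CDRs;
    charge and germline deviations must sit in frameworks (framework-only
    deviation calling would otherwise conflate them).
    """

    liabilities: tuple[tuple[str, str, int], ...] = ()  # (type, chain, position)
    hydrophobic_patches: tuple[tuple[str, str, int], ...] = ()  # (chain, residue, position)
    charge_deviations: tuple[tuple[str, int, str], ...] = ()  # (chain, position, K/R)
    germline_deviation: Optional[tuple[str, int, str]] = None  # (chain, position, to_aa)
    epitope_cores: tuple[tuple[str, int, str], ...] = ()  # (chain, position, 9-mer)
    # residues written into the germline ancestor *and all descendants* as
    # well as the Fv, e.g. to give a charge plant a hydrophilic framework
    # context or a CDR-L3 its glycines; never a deviation by construction
    force_germline: tuple[tuple[str, int, str], ...] = ()  # (chain, position, residue)


@dataclass(frozen=True)
class GroundTruth:
    """Ledger of every planted feature, for recovery assertions."""

    liabilities: tuple[tuple[str, int, str], ...]  # (chain, position, type)
    deviations: tuple[tuple[str, int, str, str], ...]  # (chain, pos, query, consensus)
    epitope_cores: tuple[tuple[str, int, str], ...]
    hydrophobic_patches: tuple[tuple[str, int, str], ...]  # (chain, position, residue)


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _clean_sequence(rng: np.random.Generator, seq: str, max_rounds: int = 50) -> str:
    """Resample residues at accidental liability anchors until a scan of
    the sequence is empty."""
    chars = list(seq)
    for _ in range(max_rounds):
        record = ChainRecord(id="tmp", sequence="".join(chars))
        hits = scan_motifs(record)
        if not hits:
            return "".join(chars)
        for hit in hits:
            idx = hit.position - 1
            chars[idx] = SAFE_ALPHABET[rng.integers(0, len(SAFE_ALPHABET))]
    raise DataError("could not clean background sequence of liability motifs")


def make_germline_set(config: SynthConfig, locus: str = "synthetic") -> GermlineSet:
    """A liability-free random ancestor plus mutated descendants.

    Descendants differ from the ancestor at ``mutation_rate`` of positions
    (uniform over the 20 residues); the ancestor is entry 0.
    """
    if config.n_germlines < 1:
        raise ConfigError("n_germlines must be >= 1")
    rng = np.random.default_rng(config.seed)
    ancestor = _clean_sequence(rng, _random_sequence(rng, config.domain_length))
    entries = [(f"{locus}V1-01", ancestor)]
    for i in range(1, config.n_germlines):
        chars = list(ancestor)
        for pos in range(len(chars)):
            if rng.random() < config.mutation_rate:
                chars[pos] = AMINO_ACIDS[rng.integers(0, 20)]
        entries.append((f"{locus}V1-{i + 1:02d}", "".join(chars)))
    return GermlineSet(entries=tuple(entries), locus="synthetic")


# motif templates with guard residues: (written string, anchor offset)
_LIABILITY_TEMPLATES = {
    "deamidation": ("NGL", 0),
    "isomerization": ("DGL", 0),
    "n_glycosylation": ("NLTL", 0),
    "o_glycosylation": ("LSSSL", 1),
    "oxidation": ("M", 0),
    "unpaired_cysteine": ("C", 0),
}


def _plant_into(chars: list[str], position: int, template: str, anchor_offset: int) -> None:
    start = position - 1 - anchor_offset
    if start < 0 or start + len(template) > len(chars):
        raise ConfigError(f"plant at position {position} does not fit the chain")
    for i, aa in enumerate(template):
        chars[start + i] = aa


def _region_of(boundaries: dict, position: int) -> str:
    for name, (s, e) in boundaries.items():
        if s <= position <= e:
            return name
    return "fr"


def make_fv(
    config: SynthConfig,
    germlines: dict[str, GermlineSet],
    plant: PlantSpec = PlantSpec(),
    boundaries: dict = DEFAULT_BOUNDARIES,
    name: str = "synthFv",
) -> tuple[FvPair, GroundTruth]:
    """Derive an Fv from the germline ancestors and plant the requested
    features, verifying exact detector recovery of the ledger.

    Planting is deterministic given the germline sets, so a verification
    failure here is final; ``make_case`` wraps this with fresh germline
    draws inside a bounded retry budget.
    """
    return _make_fv_once(config, germlines, plant, boundaries, name)


def _validate_plant(plant: PlantSpec, boundaries: dict) -> None:
    for liab_type, chain, pos in plant.liabilities:
        if _region_of(boundaries[chain], pos) == "fr":
            raise ConfigError(f"liability plant at {chain}:{pos} must be inside a CDR")
    for chain, aa, pos in plant.hydrophobic_patches:
        if aa not in "ILVFMW":
            raise ConfigError("hydrophobic patch residue must be aliphatic/aromatic")
        if _region_of(boundaries[chain], pos) == "fr":
            raise ConfigError("hydrophobic patch must be inside a CDR")
    for chain, pos, aa in plant.force_germline:
        if aa not in SAFE_ALPHABET:
            raise ConfigError(f"forced background residue {aa!r} is not liability-safe")
    for chain, pos, aa in plant.charge_deviations:
        if aa not in "KR":
            raise ConfigError("charge deviation residue must be K or R")
        if _region_of(boundaries[chain], pos) != "fr":
            raise ConfigError("charge deviations must be framework")
    if plant.germline_deviation:
        chain, pos, aa = plant.germline_deviation
        if _region_of(boundaries[chain], pos) != "fr":
            raise ConfigError("germline deviation must be framework")
    for chain, pos, core in plant.epitope_cores:
        if len(core) != CORE_LENGTH:
            raise ConfigError("epitope core must be a 9-mer")
        region = boundaries[chain]
        in_one_cdr = any(
            s <= pos and pos + CORE_LENGTH - 1 <= e for s, e in region.values()
        )
        if not in_one_cdr:
            raise ConfigError("epitope core must fit inside a single CDR")


def apply_forced_background(
    germlines: dict[str, GermlineSet], plant: PlantSpec
) -> dict[str, GermlineSet]:
    """Write forced residues into every entry of the germline sets."""
    if not plant.force_germline:
        return germlines
    out = {}
    for which, gl in germlines.items():
        entries = []
        for gname, seq in gl.entries:
            chars = list(seq)
            for chain, pos, aa in plant.force_germline:
                if chain == which:
                    chars[pos - 1] = aa
            entries.append((gname, "".join(chars)))
        out[which] = GermlineSet(entries=tuple(entries), locus=gl.locus)
    return out


def _make_fv_once(config, germlines, plant, boundaries, name) -> tuple[FvPair, GroundTruth]:
    _validate_plant(plant, boundaries)
    germlines = apply_forced_background(germlines, plant)
    seqs = {which: list(germlines[which].sequences[0]) for which in ("heavy", "light")}
    truth_liab = []
    truth_dev = []

    for liab_type, chain, pos in plant.liabilities:
        template, offset = _LIABILITY_TEMPLATES[liab_type]
        _plant_into(seqs[chain], pos, template, offset)
        truth_liab.append((chain, pos, liab_type))
    for chain, aa, pos in plant.hydrophobic_patches:
        seqs[chain][pos - 1] = aa
    for chain, pos, aa in plant.charge_deviations:
        base = seqs[chain][pos - 1]
        if base == aa:
            # background coincidence, not a config mistake: retryable
            raise DataError(f"charge plant at {chain}:{pos}: base residue is already {aa}")
        seqs[chain][pos - 1] = aa
        truth_dev.append((chain, pos, aa, base))
    if plant.germline_deviation:
        chain, pos, aa = plant.germline_deviation
        base = seqs[chain][pos - 1]
        if base == aa:
            raise DataError(f"deviation plant at {chain}:{pos}: base residue is already {aa}")
        seqs[chain][pos - 1] = aa
        truth_dev.append((chain, pos, aa, base))
    for chain, pos, core in plant.epitope_cores:
        for i, aa in enumerate(core):
            seqs[chain][pos - 1 + i] = aa

    chains = {}
    for which in ("heavy", "light"):
        record = ChainRecord(
            id=f"{name}_{which[0].upper()}",
            sequence="".join(seqs[which]),
            chain_type=which,
        )
        chains[which] = annotate_regions(record, boundaries[which])
    fv = FvPair(heavy=chains["heavy"], light=chains["light"], name=name)
    truth = GroundTruth(
        liabilities=tuple(sorted(truth_liab)),
        deviations=tuple(sorted(truth_dev)),
        epitope_cores=tuple(plant.epitope_cores),
        hydrophobic_patches=tuple(
            (chain, pos, aa) for chain, aa, pos in plant.hydrophobic_patches
        ),
    )
    _verify(fv, germlines, truth, config)
    return fv, truth


def _verify(fv: FvPair, germlines, truth: GroundTruth, config: SynthConfig) -> None:
    """Exact-recovery check of the ledger; raises DataError on mismatch."""
    found_liab = []
    found_dev = []
    for which in ("heavy", "light"):
        chain = fv.chain(which)
        for hit in scan_motifs(chain):
            found_liab.append((which, hit.position, hit.liability_type))
        ranked = rank_germlines(chain, germlines[which])
        cons = consensus_profile(ranked[: config.top_k], query_id=chain.id)
        for pos, query_aa, cons_aa in deviations(
            chain, cons, min_conservation=config.min_conservation
        ):
            found_dev.append((which, pos, query_aa, cons_aa))
    if tuple(sorted(found_liab)) != truth.liabilities:
        raise DataError(
            f"accidental liability content: planted {truth.liabilities}, found {found_liab}"
        )
    if tuple(sorted(found_dev)) != truth.deviations:
        raise DataError(
            f"accidental deviations: planted {truth.deviations}, found {found_dev}"
        )
    for which, pos, core in truth.epitope_cores:
        seq = fv.chain(which).sequence
        if seq.count(core) != 1 or seq.find(core) != pos - 1:
            raise DataError("planted epitope core not unique at its position")
        for g in germlines[which].sequences:
            if core in g:
                raise DataError("planted epitope core occurs in a germline entry")


@dataclass(frozen=True)
class SynthCase:
    """A fully verified fixture: Fv, germline sets, PSSMs, ground truth."""

    fv: FvPair
    germlines: dict[str, GermlineSet]
    pssms: tuple[AllotypePSSM, ...]
    truth: GroundTruth
    config: SynthConfig


def make_case(
    config: SynthConfig,
    plant: PlantSpec = PlantSpec(),
    boundaries: dict = DEFAULT_BOUNDARIES,
    n_allotypes: int = 4,
    name: str = "synthFv",
) -> SynthCase:
    """Draw germline sets and an Fv together, verify exact recovery of
    every planted feature (including the epitope scan against the
    generated PSSMs), and redraw with a fresh sub-seed on any accidental
    detection, within the configured retry budget."""
    last_error: Optional[Exception] = None
    for attempt in range(config.max_retries):
        sub = SynthConfig(
            seed=int(np.random.default_rng((config.seed, attempt)).integers(2**31)),
            n_germlines=config.n_germlines,
            domain_length=config.domain_length,
            mutation_rate=config.mutation_rate,
            top_k=config.top_k,
            min_conservation=config.min_conservation,
            max_retries=config.max_retries,
        )
        germlines = {
            "heavy": make_germline_set(
                SynthConfig(seed=sub.seed * 2 + 1, n_germlines=sub.n_germlines,
                            domain_length=sub.domain_length, mutation_rate=sub.mutation_rate),
                locus="IGHV",
            ),
            "light": make_germline_set(
                SynthConfig(seed=sub.seed * 2 + 2, n_germlines=sub.n_germlines,
                            domain_length=sub.domain_length, mutation_rate=sub.mutation_rate),
                locus="IGKV",
            ),
        }
        germlines = apply_forced_background(germlines, plant)
        try:
            fv, truth = make_fv(config, germlines, plant, boundaries, name=name)
            pssms = _case_pssms(sub.seed, truth, n_allotypes)
            _verify_epitopes(fv, germlines, pssms, truth)
            return SynthCase(
                fv=fv, germlines=germlines, pssms=tuple(pssms), truth=truth, config=config
            )
        except DataError as exc:
            last_error = exc
    raise DataError(f"fixture retry budget exhausted: {last_error}")


def _case_pssms(seed: int, truth: GroundTruth, n_allotypes: int) -> list[AllotypePSSM]:
    if truth.epitope_cores:
        out = []
        for i, (_, _, core) in enumerate(truth.epitope_cores):
            out.extend(make_pssms(seed + i, core, n_allotypes))
        return out
    # no planted binder: matrices target a decoy core absent from the Fv
    rng = np.random.default_rng((seed, 13))
    decoy = "".join(SAFE_ALPHABET[i] for i in rng.integers(0, len(SAFE_ALPHABET), size=9))
    return make_pssms(seed, decoy, n_allotypes)


def _verify_epitopes(fv: FvPair, germlines, pssms, truth: GroundTruth) -> None:
    from .epitopes import germline_filter, scan_epitopes

    for which in ("heavy", "light"):
        chain = fv.chain(which)
        _, filtered = germline_filter(scan_epitopes(chain, pssms), germlines[which])
        expected = [pos for c, pos, _ in truth.epitope_cores if c == which]
        if sorted(h.start for h in filtered) != sorted(expected):
            raise DataError(
                f"epitope scan on {which} found {[h.start for h in filtered]}, "
                f"expected {expected}"
            )


# CDR anchor slots whose full template span [pos-1, pos+3] stays inside
# the CDR (a guard residue written into framework would register as a
# germline deviation), plus framework slots clear of CDR edges.
LIABILITY_SLOTS = (("heavy", 28), ("heavy", 53), ("light", 52), ("light", 91), ("light", 95))
DEVIATION_SLOTS = (("heavy", 5, "K"), ("light", 5, "R"), ("light", 70, "P"))
CORE_SLOTS = (("heavy", 95), ("light", 25))


def random_recovery_plant(
    rng: np.random.Generator, n_liabilities: int, n_cores: int, n_deviations: int
) -> PlantSpec:
    """A randomised PlantSpec for detector-recovery studies.

    Plants ``n_liabilities`` motifs of random type into fixed CDR slots
    (up to 5), ``n_cores`` epitope 9-mers (up to 2, one per chain), and
    ``n_deviations`` framework deviations (up to 3: two charge plants and
    one Pro deviation).
    """
    if not (0 <= n_liabilities <= len(LIABILITY_SLOTS)):
        raise ConfigError("n_liabilities out of range")
    if not (0 <= n_cores <= len(CORE_SLOTS)):
        raise ConfigError("n_cores out of range")
    if not (0 <= n_deviations <= len(DEVIATION_SLOTS)):
        raise ConfigError("n_deviations out of range")
    types = list(_LIABILITY_TEMPLATES)
    slots = [LIABILITY_SLOTS[i] for i in rng.permutation(len(LIABILITY_SLOTS))[:n_liabilities]]
    liabilities = tuple(
        (types[rng.integers(len(types))], chain, pos) for chain, pos in slots
    )
    cores = tuple(
        (chain, pos, "".join(SAFE_ALPHABET[i] for i in rng.integers(0, len(SAFE_ALPHABET), 9)))
        for chain, pos in CORE_SLOTS[:n_cores]
    )
    charge = tuple((c, p, aa) for c, p, aa in DEVIATION_SLOTS[:n_deviations] if aa in "KR")
    germ_dev = None
    if n_deviations == 3:
        c, p, aa = DEVIATION_SLOTS[2]
        germ_dev = (c, p, aa)
    return PlantSpec(
        liabilities=liabilities,
        charge_deviations=charge,
        germline_deviation=germ_dev,
        epitope_cores=cores,
    )


DEMO_BOUNDARIES = {
    "heavy": DEFAULT_BOUNDARIES["heavy"],
    "light": {"cdr1": (24, 34), "cdr2": (50, 56), "cdr3": (89, 98)},
}


def make_demo_fv(seed: int = 0) -> FvPair:
    """A synthetic stand-in for a developability-challenged lead Fv.

    Carries the classic defect residues at canonical sequential positions:
    an exposed Ile31 in LCDR1 and Val96 in LCDR3, framework Arg16 and
    Lys76 in the heavy chain, an Asn53-Asp54-Gly55 PTM context in HCDR2,
    and a framework Pro88; the LCDR3 is ten residues long, Pro-free and
    carries two glycines. The background is drawn from the liability-safe
    alphabet so the planted features are the only motifs present.
    """
    rng = np.random.default_rng((seed, 31))
    heavy = list(_random_sequence(rng, 110, SAFE_ALPHABET))
    light = list(_random_sequence(rng, 100, SAFE_ALPHABET))
    no_pro = SAFE_ALPHABET.replace("P", "")
    for i in range(88, 98):  # keep the LCDR3 Pro-free so Pro96 is a design move
        if light[i] == "P":
            light[i] = no_pro[rng.integers(0, len(no_pro))]
    heavy[15] = "R"   # Arg16: surplus surface charge
    heavy[52:55] = list("NDG")  # Asn53-Asp54-Gly55: deamidation/isomerization context
    heavy[75] = "K"   # Lys76: surplus surface charge
    heavy[87] = "P"   # Pro88: germline-consensus deviation
    light[30] = "I"   # Ile31 in LCDR1
    light[95] = "V"   # Val96 in LCDR3
    light[90], light[92] = "G", "G"  # the two flexible LCDR3 glycines
    h = ChainRecord(id="demoFv_H", sequence="".join(heavy), chain_type="heavy")
    l = ChainRecord(id="demoFv_L", sequence="".join(light), chain_type="light")
    return FvPair(
        heavy=annotate_regions(h, DEMO_BOUNDARIES["heavy"]),
        light=annotate_regions(l, DEMO_BOUNDARIES["light"]),
        name="demoFv",
    )


def make_toy_structure(
    seed: int, fv: FvPair, mode: str = "extended", compaction: float = 1.0
) -> StructureModel:
    """Idealised Calpha/Cbeta trace for an Fv.

    ``extended``: consecutive Calpha atoms 3.8 A apart on a line, heavy
    chain (id H) and light chain (id L) laid out 30 A apart — every
    residue is surface. ``compact``: residues wound onto a dense spherical
    spiral (scaled by ``compaction``; smaller = denser) so interior
    residues acquire many neighbors and read as buried.
    """
    if mode not in ("extended", "compact"):
        raise ConfigError(f"unknown structure mode {mode!r}")
    rng = np.random.default_rng((seed, 7))
    atoms: list[Atom] = []
    offsets = {"heavy": ("H", np.array([0.0, 0.0, 0.0])), "light": ("L", np.array([0.0, 30.0, 0.0]))}
    total = len(fv.heavy) + len(fv.light)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    counter = 0
    for which in ("heavy", "light"):
        chain_id, origin = offsets[which]
        seq = fv.chain(which).sequence
        for i, aa in enumerate(seq):
            if mode == "extended":
                ca = origin + np.array([3.8 * i, 0.0, 0.0])
            else:
                # spherical Fibonacci ball: radius grows with index^(1/3)
                t = counter + 0.5
                r = 6.5 * compaction * (t / total) ** (1.0 / 3.0)
                theta = golden * t
                z = 1.0 - 2.0 * t / total
                rho = np.sqrt(max(0.0, 1.0 - z * z))
                # both chains share one dense ball to create a buried core
                ca = r * np.array([rho * np.cos(theta), rho * np.sin(theta), z])
            ca = ca + rng.normal(0.0, 0.01, size=3)
            res_name = seq3(aa).upper()
            atoms.append(Atom(chain_id, i + 1, res_name, "CA", "C", *ca))
            if aa != "G":
                cb = ca + np.array([0.0, 0.0, 1.53])
                atoms.append(Atom(chain_id, i + 1, res_name, "CB", "C", *cb))
            counter += 1
    return StructureModel(atoms=tuple(atoms))


def make_pssms(
    seed: int, target_core: str, n_allotypes: int = 4, threshold: float = 12.0
) -> list[AllotypePSSM]:
    """Synthetic allotype matrices that bind ``target_core`` by a wide,
    constructed margin and score random 9-mers below threshold with
    probability >= 0.99.

    The target residue earns +2 at each position (core score 18); every
    other residue draws from [-8, -4], so a single mismatch already caps
    the score at 16 - 4 = 12, at or below the threshold of 12. Binding is
    strict, so only the exact core binds — a point substitution in the
    core destroys the epitope and cannot create a new one elsewhere.
    """
    if len(target_core) != CORE_LENGTH:
        raise ConfigError("target core must be a 9-mer")
    rng = np.random.default_rng((seed, 11))
    groups = ("DRB1", "DR345", "DQ", "DP")
    out = []
    for a in range(n_allotypes):
        matrix = []
        for p in range(CORE_LENGTH):
            row = [-float(rng.uniform(4.0, 8.0)) for _ in range(20)]
            row[AMINO_ACIDS.index(target_core[p])] = 2.0
            matrix.append(tuple(row))
        group = groups[a % len(groups)]
        out.append(
            AllotypePSSM(
                allotype=f"{group}*syn:{a + 1:02d}",
                matrix=tuple(matrix),
                threshold=threshold,
                group=group,
            )
        )
    return out
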