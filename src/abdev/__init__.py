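"""abdev: antibody Fv developability profiling and variant design.

Profiles a variable-domain pair for PTM liability motifs, aggregation
propensity, charge and isoelectric point, germline deviation, and HLA
class II epitope content; proposes and ranks point-substitution variants
under conservative design rules.
"""

from .seqcore import (
    ChainRecord,
    Edit,
    FvPair,
    RegionMap,
    annotate_regions,
    apply_edits,
    diff,
    read_fasta,
    write_fasta,
)
from .germline import (
    ConsensusProfile,
    GermlineAlignment,
    GermlineSet,
    ScoringScheme,
    align_global,
    consensus_profile,
    deviations,
    rank_germlines,
)
from .liabilities import (
    LiabilityHit,
    LiabilityRule,
    default_rules,
    gate_by_exposure,
    liability_delta,
    scan_motifs,
)
from .structure import (
    ExposureProfile,
    StructureModel,
    compute_exposure,
    default_exposure,
    neighbor_exposure,
    read_pdb,
    relative_exposure,
    residue_sasa,
    sasa,
    write_pdb,
)
from .biophys import (
    AggregationProfile,
    ChargeModel,
    PropensityScales,
    aggregation_profile,
    conformational_profile,
    hotspots,
    intrinsic_profile,
    isoelectric_point,
    net_charge,
    surface_profile,
    window_profile,
)
from .epitopes import (
    AllotypePSSM,
    EpitopeCluster,
    EpitopeHit,
    cluster,
    epitope_delta,
    filtered_clusters,
    germline_filter,
    read_pssms,
    scan_epitopes,
    write_pssms,
)
from .design import (
    CandidateEdit,
    DesignConfig,
    FvContext,
    PositionClass,
    VariantReport,
    assemble_variants,
    classify_positions,
    filter_candidates,
    propose,
    rank_variants,
)
from .synth import (
    GroundTruth,
    PlantSpec,
    SynthCase,
    SynthConfig,
    make_case,
    make_demo_fv,
    make_fv,
    make_germline_set,
    make_pssms,
    make_toy_structure,
)

__version__ = "0.1.0"
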