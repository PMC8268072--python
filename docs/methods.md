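# Methods

This note records the models, parameter choices and numerical conventions
behind `abdev`, and what the synthetic test bed does and does not
establish about real antibodies.

## Sequence model and numbering

Positions are 1-based sequential indices per chain. The toolkit does not
implement Kabat/IMGT/Chothia renumbering: CDR boundaries are supplied as
configuration (`regions.yaml`), and any position quoted from the
literature must already be resolved to a sequential index. This keeps the
core free of a numbering HMM and makes every report unambiguous, at the
cost of requiring a one-time boundary mapping per antibody. The design
space is substitution-only; `diff` rejects length changes because every
design move the toolkit proposes is a point substitution.

## Liability scanning

Each rule is a small token pattern (anchor residue plus follower class,
or an `N-X-S/T`-style template, or a homogeneous-run rule). Defaults:

| class | pattern | base severity |
|---|---|---|
| deamidation | `N[GSTA]` | medium |
| isomerization | `D[GSDT]` | medium |
| N-glycosylation | `N[^P][ST]` | medium |
| O-glycosylation | `run:ST:3` | low |
| oxidation | `M`, `W` | medium |
| unpaired cysteine | any `C` off the whitelist | medium |

Hits anchored in a CDR escalate to high severity (a modification at the
binding interface can abolish function); rules marked low stay low.
Follower sets are deliberately configuration: degradation chemistry is
context-dependent and vendors disagree on the exact sets. The worked
D→E example uses an extended deamidation follower set including `D`
(`ND` is a known slow deamidation motif), under which a single Asp
substitution in an `N-D-G` context removes a deamidation and an
isomerization motif at once. Exposure gating annotates rather than
deletes: buried hits are demoted to low severity because burial slows,
but does not prevent, the chemistry. Without a structure every residue is
treated as exposed — conservative over-reporting.

## Aggregation surrogate

The propensity score is an openly specified member of the
Zyggregator-style family, not a reimplementation of any proprietary tool:

    a(i) = w_h·z_H + w_b·z_B − w_a·z_A − w_q·|q|

with Kyte–Doolittle hydropathy, Chou–Fasman β and α preferences (each
z-scored over the 20 residues) and formal side-chain charge at pH 7
(+1 K/R, −1 D/E, +0.1 H). Default weights are w_h = 1.0, w_b = 0.6,
w_a = 0.4, w_q = 1.0: β-structure drives self-association more strongly
than helicity protects. With these defaults every residue in
{I, L, V, F, M, W} scores strictly above Ser, so the
hydrophobicity-reduction design move can never raise the intrinsic track
— the ordering is a property of the published scale tables under this
weighting, and all weights and scales are configurable for
re-calibration.

`A_res` is the mean of `a` over the 7-mer window centred at each
position (truncated at the ends; a window longer than the chain
degenerates to the global mean). Totals are positive-part sums
(`Σ max(·, 0)`): aggregation is driven by hotspots and should not be
offset by strongly protective regions; plain sums are available by flag.
The conformational correction is exposure weighting
(`S_res = A_res · exposure`), and the surface track accumulates
exposure-weighted intrinsic scores over a spatial patch (10 Å between
representative atoms; a ±4 sequence window when no structure is given).
The 10 Å radius and the window width are choices, not derived values.
Hotspots are maximal runs of ≥3 positions at or above mean + 1 SD of
their track; a constant track has no hotspots by definition.

## Solvent exposure

Shrake–Rupley SASA with a 1.4 Å probe and 960 golden-spiral sphere
points per atom; van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å
(default 1.70). Sample points lying on or inside a neighbouring expanded
sphere count as occluded (with a 1e-9 relative slack), so coincident
identical atoms fully occlude each other. Relative exposure divides
per-residue SASA by the theoretical Gly-X-Gly maxima (Tien et al.),
clamped to [0, 1] since terminal residues can exceed the reference. For
reduced representations the neighbour-count surrogate is used:
exposure = max(0, 1 − n/20) with neighbours counted among representative
atoms (Cβ, Cα for Gly) within 10 Å. Precedence: Shrake–Rupley when a
structure is given, neighbour count for sparse models, fully-exposed for
sequence-only runs. The PDB reader is deliberately strict — a coordinate
field that fails to parse raises with its line number rather than being
coerced — because silently corrupt exposure values are worse than a hard
failure.

## Charge and isoelectric point

Henderson–Hasselbalch sums over pKa values N-term 8.6, C-term 3.6,
D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5, termini counted once
per chain (an Fv counts both chains' termini). The pI is found by
bisection on (0, 14) to |charge| < 1e-4, which lands within 0.01 pH of
the true zero crossing. Computed pI values are sequence-level estimates:
glycosylation and folding shift measured (cIEF) values, so only
orderings and shifts between variants are meaningful, never absolute
agreement with instrument readings.

## Germline comparison

Pairwise Gotoh affine-gap global alignment, BLOSUM62, gap open 10 /
extend 1 in the positive-penalty convention (a gap of length L costs
10 + L). Traceback ties break deterministically: diagonal, then up, then
left. Identity is computed over columns where both symbols are residues.
The consensus profile uses the top-5 germlines by identity (ties by
score, then name); conservation is the modal residue's frequency out of
k, with gap-aligned germlines counting against it, and modal ties break
lexicographically. Deviation calling is framework-only by default —
the germline-reversion design family operates on frameworks — with CDRs
available by flag, and requires conservation ≥ 0.7.

## Epitope scanning

Additive 9-mer PSSM scoring with a strict per-allotype threshold, in the
pocket-profile tradition of class II predictors; flanking residues are
ignored. Germline whitelisting is substring-exact at 9-mer granularity:
a core occurring verbatim in any supplied germline is treated as
non-immunogenic. Clustering is single-linkage over cores sharing ≥1
position; cluster breadth counts distinct allotypes. Cluster sets of a
parent/variant pair are compared by span, and any created cluster flags
the variant. The package ships no real allotype matrices — scoring
mechanics are generic, matrices are data.

## Design rules

Classification: Critical = CDR, configured interface position, or
buried (exposure < 0.25) germline-unanimous position; Contributing =
buried packing or within ±2 of a CDR boundary; else Neutral. CDR edits
are allowed only for the hydrophobicity, PTM-removal and flexibility
families (the families that legitimately operate inside CDRs), and only
where the position is Critical for being CDR alone.

Filtering recomputes each candidate's full effect (liability keys,
epitope cluster spans, aggregation totals, pI, germline identity) on the
edited chain rather than trusting local reasoning; exposure is reused
from the parent on the assumption that a point substitution does not
refold the domain. The A_tot tolerance defaults to 0 (strict
non-increase). Charge-removal edits necessarily raise the *intrinsic*
score locally (the protective |q| penalty disappears), so they pass the
strict filter only where the surrounding windowed track stays
non-positive — which is exactly the hydrophilic framework context in
which such edits are sensible.

Ranking is lexicographic: epitope clusters created, liability count,
T_tot, A_tot, then descending germline identity, then name — safety
criteria before propensity scores, reflecting that a new T-cell epitope
or PTM is a categorical defect while aggregation scores are graded. The
multi-edit lead takes admissible edits round-robin across families (one
per position, ≤6 by default) so it addresses every defect class instead
of accumulating six variations of one.

## Synthetic workbench

Backgrounds are drawn uniformly over the 20 residues and then cleaned by
resampling residues at accidental motif anchors (from a liability-safe
alphabet) until a scan is empty; planted motifs carry guard residues so
they cannot merge with their surroundings. Fixture assembly
(`make_case`) verifies every detector against the ledger — exact
liability keys, exact framework deviations, unique epitope core
placement, no germline containing the planted core — and redraws the
germline sets with a fresh derived seed on any accident, within a
bounded retry budget. Liability slots used by the recovery fixtures keep
the whole motif template inside a CDR, because a guard residue written
into framework would register as a germline deviation.

Defaults: 8 germlines per set (6 in the test suite's scaled fixtures),
domain length 110, descendant mutation rate 5 %, top-5 consensus,
conservation threshold 0.7. Synthetic PSSMs give the target core +2 per
position (score 18) against a threshold of 12 with off-target scores in
[−8, −4], so exactly the planted core binds, a single core substitution
destroys binding, and the measured false-positive rate on random 9-mers
is far below 1 %. The standard defect landscape plants two HCDR2 PTM
motifs, exposed hydrophobics in LCDR1/LCDR3, framework Arg/Lys in a
forced hydrophilic context (so charge reversions survive the strict
A_tot filter), a framework Pro at a germline-unanimous position, a
Gly-rich Pro-free LCDR3, and one non-germline HLA-II core in HCDR3. Toy
structures are idealised Cα/Cβ traces (extended line or a dense
Fibonacci ball); they exercise the exposure code paths, nothing more.

What passing tests show: the detectors find exactly what is planted,
with no false positives, under backgrounds engineered to be otherwise
clean; the design rules fire on their intended triggers and respect
their constraints; the numerics match independent oracles. What they do
not show: performance on real antibody sequences, whose backgrounds are
not clean, whose CDR boundaries are ambiguous, and whose measured
developability depends on chemistry these surrogates only rank, not
predict.

## Problem sizes

The test suite and the acceptance script use 110-residue domains,
germline sets of 5–8, 50 recovery fixtures, 1000-sequence scanner
oracles, 100-peptide pI grids, exhaustive alignment enumeration up to
length 8, and one CLI design run per invocation — sizes chosen so the
full suite completes in about two minutes on one CPU while still
exercising every contract at non-trivial scale.

## Known limitations

Sequential numbering requires externally resolved CDR boundaries; the
aggregation surrogate is a ranking tool, not a predictor of measured
aggregation onset; computed pI ignores glycans and folding; germline
whitelisting at 9-mer granularity is stricter than whole-sequence
matching; the combined variant is assembled greedily, not by exhaustive
subset search; and no real HLA matrices or germline databases are
included.
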