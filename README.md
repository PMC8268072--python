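# abdev — antibody Fv developability profiling and variant design

`abdev` is a toolkit for the computational side of therapeutic-antibody
lead optimisation. Given the heavy and light variable-domain sequences of
an antibody (and optionally a 3D model of the Fv), it profiles the
molecule for the defects that sink candidates in development — chemical
liability motifs, aggregation-prone patches, surplus surface charge,
departures from human germline, and HLA class II T-helper epitopes — and
then proposes, vets, and ranks point substitutions that remove those
defects without creating new ones. It is aimed at antibody engineers who
want a transparent, fully configurable, scriptable alternative to
black-box vendor pipelines, and at method developers who need a seeded
synthetic test bed with exact ground truth.

## What it computes

**PTM liabilities.** Rule-based motif scanning: Asn deamidation
(`N[GSTA]`), Asp isomerization (`D[GSDT]`), N-glycosylation sequons
(`N-X-S/T`, X ≠ P), O-glycosylation S/T runs, Met/Trp oxidation, and
unpaired cysteines. Follower sets are configuration, hits are labelled by
region (CDR anchors escalate in severity) and can be gated by solvent
exposure.

**Aggregation propensity.** A per-residue intrinsic score

    a(i) = w_h·z_H(aa_i) + w_b·z_B(aa_i) − w_a·z_A(aa_i) − w_q·|q(aa_i)|

combining z-scored Kyte–Doolittle hydropathy (H), Chou–Fasman β-sheet
(B) and α-helix (A) propensities with a charge penalty, smoothed over
overlapping 7-mers into `A_res` with whole-sequence total `A_tot`
(positive-part sum). The conformational correction weights the windowed
track by relative solvent exposure (`S_res`, `S_tot`); the surface track
`T_res` accumulates exposure-weighted propensity over a spatial patch
(10 Å around each residue's Cβ, or a ±4 sequence window without a
structure), totalled as `T_tot`. Hotspots are runs of ≥3 positions above
mean + 1 SD of a track.

**Charge and pI.** Henderson–Hasselbalch net charge over an EMBOSS-style
pKa table and a bisection isoelectric point, with termini counted once
per chain.

**Germline analysis.** Needleman–Wunsch affine-gap global alignment
(BLOSUM62, gap open 10 / extend 1) of each chain against a germline
V-gene set, identity ranking, a consensus profile over the top-5 most
similar germlines, and framework positions deviating from a conserved
consensus (≥ 0.7).

**HLA-II epitopes.** Every 9-mer core scored against per-allotype
position-specific scoring matrices (DRB1 / DR3-4-5 / DQ / DP groups);
strict-threshold binders clustered by overlap; cores found verbatim in
human germline sequences whitelisted as non-immunogenic. No proprietary
matrices ship with the package — any tabular PSSM set loads from TSV.

**Variant design.** Positions are classified Neutral / Contributing /
Critical from region, interface configuration, burial and germline
conservation. Five proposal families mirror the classic optimisation
moves: exposed hydrophobic CDR residues → Ser/Thr; liability anchors →
N→Q, D→E, follower→Ala; exposed off-consensus framework Lys/Arg →
consensus (lowers pI); framework germline reversions at unanimous
positions; and a canonical Pro introduced into a long, Gly-rich,
Pro-free CDR-L3. Candidates that touch a disallowed Critical position,
create any liability or epitope cluster, or raise `A_tot` are rejected;
surviving edits are assembled into single-edit variants plus one
multi-edit lead (round-robin across families, ≤ 6 edits) and ranked
lexicographically: epitope safety, then liability count, then `T_tot`,
then `A_tot`, then germline identity.

**Synthetic workbench.** Seeded generators produce germline sets,
Fv pairs with planted defects and an exact ground-truth ledger, toy
Cα/Cβ structures, and PSSMs that bind a chosen core by a constructed
margin — a complete, download-free substrate for testing every detector.

## Worked example

Generate a workbench with the standard planted defect landscape, profile
it, and design variants:

```bash
abdev synth  --seed 3 --out bench
abdev profile --fasta bench/fv.fasta --regions bench/regions.yaml \
    --germline-heavy bench/germline_heavy.fasta \
    --germline-light bench/germline_light.fasta \
    --pssms bench/pssms.tsv --out prof
abdev design  --fasta bench/fv.fasta --regions bench/regions.yaml \
    --germline-heavy bench/germline_heavy.fasta \
    --germline-light bench/germline_light.fasta \
    --pssms bench/pssms.tsv --out designs
```

`prof/profile.json` for seed 3 reports, per chain:

* heavy-chain liabilities at positions 53 (deamidation, `NG`) and 56
  (isomerization, `DG`) — exactly the two planted motifs in HCDR2;
* one heavy-chain epitope cluster spanning 95–103 with breadth 4 (the
  planted non-germline core binds all four synthetic allotypes);
* aggregation totals `A_tot` 27.58 / `T_tot` 206.41 (heavy) and 14.98 /
  114.33 (light);
* top germline identity 85.5 % (heavy, pulled down by the plants) and
  98.2 % (light); whole-Fv pI 6.80.

`designs/variants.json` ranks the combined lead first. For seed 3 its
edit list is `H:I26S, H:N53Q, H:R16G, H:P88A, L:V97P, H:F27S` — surface
hydrophobics to Ser, the deamidation anchor to Gln, the surplus Arg
reverted to the germline Gly, the framework Pro reverted to the unanimous
germline Ala, and the canonical CDR-L3 Pro — with deltas
`dliability_count −1`, `dpI −0.15`, `dA_tot −5.49`, `dT_tot −56.0`, and
no epitope clusters created.

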