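# Methods

## Detection model

A peptide bond between consecutive residues i and i+1 is accepted as a real
covalent link when both residues have complete N/CA/C backbones and the
C(i)–N(i+1) distance is ≤ 2.5 Å; anything longer is recorded as a chain
break (data, not an error), and no ω is computed across it.  ω is the
signed IUPAC torsion Cα(i)–C(i)–N(i+1)–Cα(i+1), computed with the
atan2 formulation and wrapped into (−180°, 180°].

Classification uses symmetric windows: **cis** iff |ω| ≤ 30°, **trans** iff
the circular distance from 180° is ≤ 30°, otherwise **twisted**.  The 30°
half-width is the convention of mainstream validation tools; the source
survey gives no numeric cutoff, and the windows are configurable.  Boundary
values fall inside the closed cis/trans windows, so the three labels
partition the circle.  A *cis-nonPro* record is a cis bond whose *second*
residue is anything but proline; cis-Pro bonds are counted separately.
Motif notation `X-cis-Y` puts X before the bond; marginals such as
"Gly-cis-X" exclude the homo pair (X ≠ Gly), the only reading under which
the published motif tallies (19 Gly-cis-Gly, 59 Gly-cis-X, 15 X-cis-Gly)
are mutually consistent.

Only the first model of a coordinate file is used; selenomethionine is
promoted to Met; other non-standard residues break the chain for dihedral
purposes but their atoms stay available to the clash filter.  Alternate
conformations are collapsed before any geometry: per atom name the highest
occupancy wins, ties broken alphabetically by altloc.  Author residue
numbering with insertion codes is the public key throughout.

## Reliability filters

A record is kept only if **both** flanking residues pass all per-residue
criteria (a bond has two residues; filtering residues singly would let a
half-bad bond through):

| criterion | cutoff | comparison |
|---|---|---|
| max backbone B over N, CA, C, O, CB | 40 Å² | fails if > 40 |
| real-space correlation (RSCC) | 0.7 | fails if < 0.7 |
| 2mFo−DFc map value at atoms | 1.2 σ | fails if < 1.2 |
| worst covalent-geometry \|z\| | 4 esd | fails if > 4 |
| worst vdW overlap | 0.5 Å | fails if ≥ 0.5 |

Comparisons are strict as conventionally worded, so a value exactly at
threshold passes (the clash criterion is inclusive).  In addition the
parent structure must be at < 2.0 Å resolution (2.0 exactly is excluded),
and two context patterns are fatal regardless of metrics: the bond being
the first or last intact linkage of its chain segment, and two cis-nonPro
in a row.  Non-fatal flags surfaced for human review: a ±2-residue window
containing high-B or incomplete residues ("partially disordered loop",
quantified here as the window since the source gives no number), an
identical sister chain (same ±3-residue local sequence) whose equivalent
bond is trans, a Gly in either position (no Cβ density to cross-check),
and the genuine vicinal-disulfide motif (both residues Cys, SG–SG ≤ 2.5 Å).

**Strict mode** (default) treats a missing density annotation as a failure
("missing_density") rather than a pass: the filter is designed to reject
some genuine cases but accept almost no incorrect ones.  Non-strict mode
records such criteria as "not evaluated".

Covalent-geometry z scores are computed against a reference table of
Engh & Huber-style backbone bond lengths and angles shipped in
`cisnonpro.refdata` (N–CA 1.458 ± 0.019 Å, CA–C 1.525 ± 0.021, C–O
1.231 ± 0.020, C–N 1.329 ± 0.014, CA–CB 1.530 ± 0.020; N–CA–C
111.2 ± 2.8°, CA–C–N 116.2 ± 2.0°, C–N–CA 121.7 ± 1.8°, CA–C–O
120.8 ± 1.7°).  The synthetic builder constructs backbones at exactly these
values, so an undistorted build scores z ≈ 0 by construction; the two must
change together.

The clash term is a **heavy-atom approximation** of all-atom contact
analysis (no hydrogens are placed): overlap = r₁ + r₂ − d over all heavy
atoms within 5 Å (radii C 1.70, N 1.55, O 1.52, S 1.80 Å), excluding pairs
in the same or a sequence-adjacent residue of the same chain (a proxy for
"within three covalent bonds" that avoids building a bond graph), N/O···N/O
pairs at hydrogen-bond distance (2.4–3.2 Å), and S–S pairs at disulfide
distance (≤ 2.5 Å).  Because this under- and over-estimates true all-atom
overlaps in places, the per-residue annotation table carries an optional
`clash_override` column whose value (e.g. an externally computed MolProbity
clash) replaces the computed one entirely.

Dataset construction keeps, per homology cluster, the chain minimising the
average of resolution and composite model-quality score, after removing
chains at ≥ 2.0 Å; homology clustering itself is consumed as input.

## Survey statistics

All survey numbers are recomputed from the record table plus configuration;
there is no hidden state.

*Enrichment.*  Chain-level CAZy enrichment is the fraction of distinct
record-carrying chains with ≥ 1 CAZy family over the CAZy fraction of the
reference chain set (defaults: 6765 chains, 6%).  Multi-occurrence
concentration is the fraction of all records lying in chains with > 1
record, divided by those chains' share of the reference set; it is reported
both over all multi-record chains and restricted to CAZy ones (the
published 36-fold uses the CAZy restriction).

*Frequency tiers.*  For a count k of amino acid a in one bond position and
stratum of n records, the departure is z = (k − np)/σ with p the background
frequency (default: the UniProt column shipped in `refdata`; any
two-column CSV can replace it).  The default σ is **Poisson** √(np); this
choice reproduces the published occurrence-table flag pattern for all 80
cells, whereas the binomial √(np(1−p)) alternative (available via
`sigma="binomial"`) over-flags two cells sitting just inside the 3σ
boundary.  Tiers: z ≤ −3 depleted; 3 ≤ z < 12 over-represented; z ≥ 12
extreme (the published marks distinguish 3–6σ from ≥ 12σ and print the
6–12σ cells with the 3–6σ mark, so the implemented "over" tier spans
[3, 12)).  Second-position Pro is a structural zero — forbidden by the
definition of cis-nonPro — and is exempt from flagging.  The sample sizes
are the stratum peptide totals (144 CAZy / 295 non-CAZy).

*Motif expectations.*  Under independence, E(X-cis-Y) = N·p(X)·p(Y)/(1 −
p(Pro)), the second position renormalised to exclude Pro; expectations over
all valid ordered pairs then sum to N (exactly, for an exactly-normalised
background).  The published expectation of 3.4 for Gly-cis-Gly is not
reproduced by this or any variant we enumerated (N·p² and the
Pro-renormalised form both give ≈ 2.3–2.5 for N = 439, p = 7.23%); the
package reports its own expectation and does not attempt to reconcile the
published baseline, whose derivation is unstated.

## Conformational space

Each record's local conformation is the quintet (ϕ1, ψ1, ω, ϕ2, ψ2).
Distances are circular: each per-angle difference is wrapped into [0, 180°]
and the root-mean-square over the five slots taken.  Clustering is DBSCAN
over the precomputed circular distance matrix (radius 30°, min 3 members,
both configurable), with inputs canonically sorted by record key and labels
renumbered by smallest member key, so assignments are a pure function of
the quintet set — a reproducible replacement for the interactive
cluster-picking such motifs were originally described with.  Ramachandran
region boxes (β: ϕ ∈ [−180, −45], ψ ∈ [60, 180] ∪ [−180, −150]; α:
ϕ ∈ [−100, −30], ψ ∈ [−112, −22]) are this package's own, chosen to cover
the canonical basins, and are configurable.  ω statistics use circular
mean/SD; the skew sign comes from the third central moment of deviations
wrapped around the circular mean.

## Synthetic data

*What it emulates.*  Backbones are built forward from internal coordinates
(natural extension reference frame), imposing every bond length, angle and
dihedral exactly — so built structures return their dihedral targets to
numerical precision, trans Cα–Cα spans fall in [3.7, 3.9] Å and cis spans
below 3.0 Å as analytic consequences.  Planted cis bonds use β-like
flanking conformations (ϕ1 = −120°, ψ1 = 130°, ϕ2 = −90°), matching the
observed preference of genuine cis-nonPro for strand ends and keeping the
two flanking strands from colliding across the short Cα–Cα link.  Cβ is
placed with L-chirality (improper N–C–CA–Cβ = +120°); carbonyl O in the
peptide plane.

Corruption directives mirror how misfit cis bonds present in real crystal
structures: `high_b` switches a ±2-residue window to a disordered B-factor
profile (mean 70 ± 10 Å² vs ordered 15 ± 3 Å²); `geometry_distort(k)`
stretches the first residue's N–CA bond by exactly k esd at build time (so
the injected z is exact); `clash_inject(o)` places a foreign carbon at
vdW-sum − o from the Cβ (Cα bisector direction for Gly); `terminal_cis`
and `tandem_cis` re-target ω at the diagnostic positions.  Because real
density metrics require experimental maps, RSCC and map-σ annotations are
*simulated* as draws correlated with the disorder state (ordered: RSCC
0.85–0.98, map 1.5–4σ; disordered: 0.40–0.69, 0.3–1.1σ), with ranges
straddling the filter thresholds.  Sidechains beyond Cβ, rotamers, crystal
packing and structure factors are not modelled — so passing the benchmark
shows the *filter logic* separates ordered from corrupted plants, not that
the thresholds are optimal on real data.

The benchmark scenario uses 50 chains of 24 residues: 12 clean plants, 12
decoy records (3 high-B, 3 geometry, 2 clash, 2 terminal, 1 tandem pair),
27 all-trans chains.  Sequences are drawn from the background frequencies
with Pro excluded so every planted bond is cis-nonPro.

Survey samples assign CAZy status at the reference fraction and per-chain
record counts from stratum-specific distributions; the expected chain-level
and multi-occurrence folds follow analytically from those parameters
(`expected_chain_fold`, `expected_multi_fold`), and constructors invert a
target fold into feasible rates (a chain-level fold F is feasible only if
F × CAZy-fraction ≤ 1).  Calibration in `analysis/04_fold_recovery.py`
uses 20 seeds × 5000 chains per condition, sizes at which the planted
folds 1, 4 and 36 sit comfortably inside the 95% sampling interval of the
measured folds.

## The curated-list reconstruction

The published curated list itself is not redistributable here, so
`synthetic_curated_list.py` builds a stand-in **labelled synthetic** whose
marginal tallies equal the published headline numbers (439 peptides, 378
chains, 99 CAZy chains / 144 CAZy peptides, 43 multi-record chains of
which 33 CAZy, 43 CAZy families with the big-family sizes, the Gly and Trp
motif counts, a negatively skewed ω sample).  Everything below the
marginals — which chain carries which pair, numbering, exact ω — is
invented deterministically from a seed.  Two printed numbers are mutually
inconsistent at the one-peptide level (99 CAZy chains with 33 multi-record
chains holding 77 peptides implies 143 CAZy peptides, not the stated 144);
the reconstruction keeps 99/33/144, so its multi-record CAZy chains hold
78 peptides and the multi-occurrence fold still rounds to 36.  Survey
results on this table validate the *statistics pipeline*, not the curation
of any real structure.

## Numerical choices and degenerate inputs

Torsions raise on collinear/coincident points; the signed dihedral is
invariant under atom-order reversal and negated by mirror reflection
(checked against an independent two-plane-normal formula to 10⁻⁶°).
Missing backbone atoms exclude a residue from dihedral computation and flag
it "incomplete".  Annotation tables reject duplicate residue keys,
out-of-range RSCC and malformed numbers with row context; empty cells are
absent values, never zeros.  Background frequency sets must cover exactly
the 20 standard amino acids and sum to 1 within 2×10⁻³ (the tolerance
admits published rounded percentage columns, which sum to 99.85%).
Enrichment of an empty record set is an error; a sample with no
multi-record chains has multi-fold 0.

## Known limitations

* Density metrics are consumed, never computed: the package cannot vet a
  structure without externally supplied RSCC/map values (strict mode then
  rejects, by design).
* The clash term ignores hydrogens and uses residue adjacency instead of a
  covalent bond graph; the override column is the escape hatch.
* The cross-chain consistency check requires the sister chain in the same
  file and an exact local sequence match; it does not look across entries.
* Clustering labels depend on the radius/min-members choices; the defaults
  are not tuned to separate any particular published cluster pair.
* The synthetic generator builds poly-backbone (no sidechains beyond Cβ),
  so clash scenarios probe the filter, not realistic packing.
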