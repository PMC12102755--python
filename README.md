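# cisnonpro

Detection, reliability filtering and survey statistics for **cis-nonProline
peptide bonds** in protein crystal structures.

## The problem

A peptide bond's ω dihedral (Cα(i)–C(i)–N(i+1)–Cα(i+1)) sits near 180° in
the common *trans* conformation and near 0° in the rare *cis* one.  Before
proline, *cis* occurs at ~5%; before any other residue ("cis-nonPro") it is
roughly a once-per-several-thousand-residues event — and exactly because it
is rare and easy to misfit into weak electron density, unfiltered surveys of
cis-nonPro are dominated by model-building errors.  Genuine cases, by
contrast, are overwhelmingly functional (active sites of carbohydrate-active
enzymes, vicinal disulfides, cofactor-binding Gly-cis-Gly motifs) and sit in
well-ordered structure.

This package is for structural bioinformaticians who want to curate genuine
cis-nonPro occurrences and quantify their occurrence patterns.  It provides:

* **Detection** — ω from coordinates (PDB/mmCIF via gemmi), cis/trans/
  twisted classification (±30° windows), chain-break handling, and
  cis-nonPro record extraction (`cisnonpro.geometry`).
* **Residue-level reliability filters** — a record survives only if both
  flanking residues have backbone B ≤ 40 Å², RSCC ≥ 0.7, 2mFo−DFc map value
  ≥ 1.2σ, no covalent-geometry outlier > 4 esd and no steric overlap
  ≥ 0.5 Å, the structure is at < 2.0 Å resolution, and the bond is neither
  chain-terminal nor tandem-cis — the two patterns that have always proven
  wrong (`cisnonpro.filters`).  Density metrics are consumed from annotation
  tables; clashes are a heavy-atom vdW approximation with an override column
  for externally computed all-atom values.
* **Survey statistics** — CAZy enrichment folds, per-position amino-acid
  frequency tables with σ-tier flags (z = (k − np)/√(np) against UniProt
  background frequencies), motif tallies and asymmetries, per-chain count
  histograms (`cisnonpro.survey`).
* **5-D conformational analysis** — (ϕ1, ψ1, ω, ϕ2, ψ2) quintets, a
  circular RMS metric, deterministic density-based clustering, Ramachandran
  region labels and ω distribution statistics (`cisnonpro.conformation`).
* **Synthetic ground truth** — backbones built exactly from internal
  coordinates, planted cis bonds, corruption scenarios (disorder, bond
  stretches, clashes, terminal/tandem decoys) and survey samples with
  configurable enrichment folds (`cisnonpro.synth`), so every stage is
  testable without downloading structures.

## Worked example

The numbered drivers under `analysis/` run the whole study.  Step 1
materialises a curated-list table (a synthetic reconstruction matching the
published survey's marginal tallies — see `docs/methods.md`), step 2 runs
the survey on it:

```bash
$ python analysis/01_build_curated_table.py
wrote 439 records over 378 chains -> results/curated_records.csv

$ python analysis/02_survey_statistics.py
peptides: 439 in 378 chains
CAZy chains: 99 (26%), fold 4.4 over the 6% reference
CAZy peptides: 144 (33%)
chains with >1 peptide: 43 (33 CAZy); multi-occurrence fold (CAZy): 36.4
distinct CAZy families: 43
Gly-cis-Gly 19, Gly-cis-X 59, X-cis-Gly 15; Trp-cis-X 49, X-cis-Trp 13
omega: mean -0.6 deg, sd 6.6 deg, skew sign -1
frequency cells flagged: 5 of 80
```

Reading: 26% of cis-nonPro-carrying chains are carbohydrate-active versus
6% of the reference set (>4-fold over-representation); chains with several
genuine cis-nonPro are concentrated in CAZy ~36-fold; Gly strongly prefers
the first bond position (59 vs 15), and the ω spread is tight around 0°
with a negative-side tail.

Step 3 benchmarks detection + filtering on generated structures with known
ground truth (ten 50-chain scenarios, 12 clean plants + 12 decoys each):

```bash
$ python analysis/03_detection_benchmark.py
...
mean precision 1.000, mean recall 1.000; 120/120 decoys rejected with the planted defect named
```

Steps 4–5 calibrate the enrichment estimators on sampled surveys and export
the diagnostic ψ1×ϕ2 conformational projection.

Python API in one breath:

```python
from cisnonpro import run_detect, run_survey
kept, rejected, counters = run_detect(["structure.pdb"], annotations)
report = run_survey(kept)          # every number recomputable from the table
```

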