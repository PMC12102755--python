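"""End-to-end orchestration: detect -> filter -> record table -> survey.

``run_detect`` takes coordinate files (or already-parsed structures) plus
sidecar annotation tables and produces the curated record table together
with a rejection report carrying machine-readable reasons and stage
counters.  ``run_survey`` recomputes every survey statistic from a record
table alone (plus configuration), so published-style summary numbers never
depend on hidden state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import survey as sv
from .conformation import omega_distribution_stats
from .filters import FilterThresholds, apply_reliability_filter
from .geometry import detect_cis_nonpro
from .model import (CisNonProRecord, ResidueAnnotation, Structure,
                    frame_to_records, read_residue_annotations, read_structure,
                    records_to_frame, select_conformer)
from .refdata import REFERENCE_CAZY_FRACTION, REFERENCE_CHAIN_TOTAL


@dataclass
class PipelineConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    background: sv.BackgroundFrequencies = field(
        default_factory=sv.BackgroundFrequencies.uniprot)
    reference_chain_total: int = REFERENCE_CHAIN_TOTAL
    reference_cazy_fraction: float = REFERENCE_CAZY_FRACTION
    sigma: str = "poisson"           # sigma model for frequency tiers
    cluster_radius: float = 30.0     # degrees, 5-D circular RMS
    cluster_min_members: int = 3
    strict: bool = True              # reject records lacking density metrics
    seed: int = 0


def run_detect(structures: dict[str, Structure] | list[str | Path],
               annotations: dict[str, dict] | None = None,
               chain_annotations: dict | None = None,
               config: PipelineConfig | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full detection chain: parse -> conformer-select -> peptide bonds ->
    omega classification -> cis-nonPro records -> suspect flags ->
    reliability filter.

    Returns (kept record table, rejection table with reasons, counters).
    ``structures`` may be parsed :class:`Structure` objects keyed by entry
    id or a list of coordinate-file paths.
    """
    cfg = config or PipelineConfig()
    if not isinstance(structures, dict):
        structures = {st.entry_id: st
                      for st in (read_structure(p) for p in structures)}
    structures = {k: select_conformer(s) for k, s in structures.items()}
    counters: dict[str, int] = {"structures": len(structures)}
    all_records: list[CisNonProRecord] = []
    for st in structures.values():
        records, c = detect_cis_nonpro(st, chain_annotations)
        all_records.extend(records)
        for k, v in c.items():
            counters[k] = counters.get(k, 0) + v
    kept, rejected = apply_reliability_filter(
        all_records, structures, annotations, cfg.thresholds, cfg.strict)
    counters["detected_cis_nonpro"] = len(all_records)
    counters["kept"] = len(kept)
    counters["rejected"] = len(rejected)
    kept_df = records_to_frame(kept)
    rej_rows = []
    for rec, reasons in rejected:
        rej_rows.append({"pdb": rec.pdb, "chain": rec.chain, "res1": rec.res1,
                         "aa1": rec.aa1, "res2": rec.res2, "aa2": rec.aa2,
                         "omega": rec.omega, "reasons": ";".join(reasons)})
    rejected_df = pd.DataFrame(
        rej_rows, columns=["pdb", "chain", "res1", "aa1", "res2", "aa2",
                           "omega", "reasons"])
    return kept_df, rejected_df, counters


def load_annotation_tables(paths: dict[str, str | Path]
                           ) -> dict[str, dict[tuple, ResidueAnnotation]]:
    """Read per-structure residue-annotation files into the nested mapping
    ``run_detect`` expects (entry id -> residue key -> annotation)."""
    return {entry: {a.key: a for a in read_residue_annotations(p)}
            for entry, p in paths.items()}


def run_survey(records: pd.DataFrame,
               config: PipelineConfig | None = None,
               out_dir: str | Path | None = None) -> dict:
    """Compute the full survey report from a curated record table.

    The report dictionary contains the headline totals, CAZy enrichment at
    the chain and peptide level, the multi-occurrence concentration folds
    (over all multi-record chains and restricted to CAZy ones), the
    chain-count histogram, the position frequency table with sigma tiers,
    motif tallies with the published marginals, and omega statistics.
    When ``out_dir`` is given, the tables are written as CSV and the
    scalar report as JSON.
    """
    cfg = config or PipelineConfig()
    required = {"pdb", "chain", "aa1", "aa2", "in_cazy"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    records = records.copy()
    records["in_cazy"] = records["in_cazy"].astype(bool)

    chain_counts, histogram = sv.chain_record_counts(records)
    chain_enrich = sv.cazy_enrichment(records, cfg.reference_cazy_fraction)
    multi_all = sv.multi_cis_enrichment(records, cfg.reference_chain_total)
    multi_cazy = sv.multi_cis_enrichment(records, cfg.reference_chain_total,
                                         cazy_only=True)
    freq_table = sv.aa_frequency_table(records, cfg.background, cfg.sigma)
    tally = sv.motif_tally(records, cfg.background)

    families = set()
    for fam in records.loc[records["in_cazy"], "cazy_family"].dropna():
        families.update(f for f in str(fam).split(";") if f)

    report = {
        "n_peptides": int(len(records)),
        "n_chains": int(chain_counts.size),
        "n_cazy_chains": chain_enrich.observed_count,
        "cazy_chain_fraction": chain_enrich.observed_fraction,
        "cazy_chain_fold": chain_enrich.fold,
        "n_cazy_peptides": int(records["in_cazy"].sum()),
        "cazy_peptide_fraction": float(records["in_cazy"].mean()),
        "n_multi_chains": int((chain_counts > 1).sum()),
        "n_multi_cazy_chains": multi_cazy.background_count,
        "multi_records": multi_all.observed_count,
        "multi_cazy_records": multi_cazy.observed_count,
        "multi_cis_fold": multi_all.fold,
        "multi_cis_fold_cazy": multi_cazy.fold,
        "chain_histogram": histogram,
        "n_cazy_families": len(families),
        "gly_cis_gly": sv.pair_count(records, "GLY", "GLY"),
        "gly_cis_x": sv.motif_marginal(records, "GLY", "first"),
        "x_cis_gly": sv.motif_marginal(records, "GLY", "second"),
        "trp_cis_x": sv.motif_marginal(records, "TRP", "first"),
        "x_cis_trp": sv.motif_marginal(records, "TRP", "second"),
    }
    if "omega" in records.columns and records["omega"].notna().sum() >= 2:
        report["omega_stats"] = omega_distribution_stats(
            records["omega"].dropna().tolist())

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        freq_table.to_csv(out / "frequency_table.csv", index=False)
        tally.to_csv(out / "motif_tally.csv", index=False)
        chain_counts.rename("n_records").to_csv(out / "chain_counts.csv")
        (out / "survey_report.json").write_text(
            json.dumps(report, indent=2, default=float))

    report["frequency_table"] = freq_table
    report["motif_tally"] = tally
    return report


def survey_from_table(path: str | Path, aliases: dict[str, str] | None = None,
                      config: PipelineConfig | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Convenience wrapper: read a record CSV/TSV (mapping external column
    headers through ``aliases``) and run the survey on it."""
    from .model import read_record_table
    return run_survey(read_record_table(path, aliases), config, out_dir)
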