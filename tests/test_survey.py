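"""Enrichment folds, sigma-tier frequency tables and motif tallies."""

import math

import numpy as np
import pandas as pd
import pytest

from cisnonpro.refdata import AA3, PUBLISHED_POSITION_TOTALS, UNIPROT_FREQUENCIES
from cisnonpro.survey import (BackgroundFrequencies, aa_frequency_table,
                              cazy_enrichment, chain_record_counts,
                              expected_pair_count, frequency_z, motif_marginal,
                              motif_tally, multi_cis_enrichment, pair_count,
                              published_flag_mismatches, tier_for)
from cisnonpro.synth import SurveySampleParams, sample_survey_dataset
from cisnonpro.synthetic_curated_list import synthetic_curated_list


@pytest.fixture(scope="module")
def curated():
    records, chains = synthetic_curated_list(seed=0)
    return records


def small_records(rows):
    return pd.DataFrame(rows, columns=["pdb", "chain", "aa1", "aa2", "in_cazy",
                                       "cazy_family"])


class TestCazyEnrichment:
    def test_all_cazy_chains_against_half_background(self):
        rec = small_records([("p1", "A", "GLY", "SER", True, "GH1"),
                             ("p2", "A", "TRP", "GLU", True, "GH5")])
        res = cazy_enrichment(rec, reference_cazy_fraction=0.5)
        assert res.fold == pytest.approx(2.0)

    def test_published_chain_counts_exceed_fourfold(self):
        # 99 of 378 record chains in CAZy vs a 6% reference fraction
        rec = small_records(
            [(f"p{i}", "A", "GLY", "SER", i < 99, "GH1" if i < 99 else "")
             for i in range(378)])
        res = cazy_enrichment(rec, reference_cazy_fraction=0.06)
        assert res.observed_fraction == pytest.approx(99 / 378)
        assert res.fold > 4.0

    def test_null_sample_fold_near_one(self):
        params = SurveySampleParams.with_chain_fold(1.0, n_chains=4000)
        folds = [cazy_enrichment(sample_survey_dataset(params, seed=s)[0],
                                 params.cazy_fraction).fold
                 for s in range(8)]
        lo, hi = np.quantile(folds, [0.0, 1.0])
        assert lo < 1.0 < hi + 0.25  # null fold within sampling spread of 1

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            cazy_enrichment(small_records([]), 0.06)


class TestMultiCisEnrichment:
    def test_published_arithmetic_rounds_to_36(self):
        # 77 of 439 peptides in 33 chains of a 6765-chain reference
        rows = []
        for c in range(33):
            rows += [(f"m{c}", "A", "GLY", "SER", True, "GH1")] * (3 if c < 11 else 2)
        n_multi = len(rows)  # 77
        rows += [(f"s{i}", "A", "ALA", "SER", False, "") for i in range(439 - n_multi)]
        rec = small_records(rows)
        res = multi_cis_enrichment(rec, reference_chain_total=6765)
        assert res.observed_count == 77
        assert res.background_count == 33
        assert round(res.fold) == 36

    def test_all_singletons_gives_zero_fold(self):
        rec = small_records([(f"p{i}", "A", "GLY", "SER", False, "")
                             for i in range(10)])
        res = multi_cis_enrichment(rec, reference_chain_total=1000)
        assert res.observed_count == 0 and res.fold == 0.0

    def test_cazy_only_restriction(self, curated):
        res_all = multi_cis_enrichment(curated, 6765)
        res_cazy = multi_cis_enrichment(curated, 6765, cazy_only=True)
        assert res_cazy.background_count == 33
        assert res_cazy.observed_count <= res_all.observed_count


class TestFrequencyTable:
    def test_cell_totals_conserve_records(self, curated):
        table = aa_frequency_table(curated)
        assert table["count"].sum() == 2 * len(curated)
        assert len(table) == 80

    def test_second_position_pro_is_structural_zero(self, curated):
        table = aa_frequency_table(curated)
        pro2 = table[(table.aa == "PRO") & (table.position == "second")]
        assert (pro2["count"] == 0).all()
        assert (pro2["tier"] == "none").all()

    def test_tier_rule_examples(self):
        # Gly first-position in the published non-CAZy stratum: 77 of 295
        z = frequency_z(77, 295, 0.0723, "binomial")
        assert z >= 12 and tier_for(z) == "over_12sigma"
        # Leu in the published CAZy first column: 1 of 144
        z_leu = frequency_z(1, 144, 0.0985)
        assert tier_for(z_leu) == "depleted_3sigma"
        # a count at expectation is unflagged
        assert tier_for(frequency_z(round(144 * 0.0673), 144, 0.0673)) == "none"

    def test_published_flags_reproduced_by_poisson_sigma(self):
        assert published_flag_mismatches("poisson") == []

    def test_binomial_sigma_overflags_two_boundary_cells(self):
        mm = published_flag_mismatches("binomial")
        cells = {(m["aa"], m["stratum"], m["position"]) for m in mm}
        assert cells == {("LEU", "non_cazy", "second"),
                         ("ASP", "non_cazy", "first")}

    def test_null_survey_flags_rare(self):
        params = SurveySampleParams.with_chain_fold(1.0, n_chains=5000)
        fractions = []
        for s in range(10):
            rec, _ = sample_survey_dataset(params, seed=100 + s)
            table = aa_frequency_table(rec)
            fractions.append((table.tier != "none").mean())
        assert np.mean(fractions) <= 0.01


class TestMotifTally:
    def test_curated_marginals_match_published_tallies(self, curated):
        assert pair_count(curated, "GLY", "GLY") == 19
        assert motif_marginal(curated, "GLY", "first") == 59
        assert motif_marginal(curated, "GLY", "second") == 15
        assert motif_marginal(curated, "TRP", "first") == 49
        assert motif_marginal(curated, "TRP", "second") == 13
        assert pair_count(curated, "TRP", "TRP") == 0

    def test_empty_records_give_empty_tally(self):
        assert len(motif_tally(small_records([]))) == 0

    def test_expected_pair_counts_normalise_to_n(self):
        # with an exactly normalised background the expectations over all
        # valid ordered pairs partition the record total
        raw = dict(UNIPROT_FREQUENCIES)
        total_p = sum(raw.values())
        bg = BackgroundFrequencies({k: v / total_p for k, v in raw.items()},
                                   source="normalised")
        n = 439
        total = sum(expected_pair_count(n, a1, a2, bg)
                    for a1 in AA3 for a2 in AA3)
        assert total == pytest.approx(n, abs=1e-6 * n)

    def test_partner_counts_are_symmetric_lookups(self, curated):
        tally = motif_tally(curated).set_index(["aa1", "aa2"])
        gly_ser = tally.loc[("GLY", "SER")]
        if ("SER", "GLY") in tally.index:
            assert gly_ser["partner_count"] == tally.loc[("SER", "GLY")]["count"]


class TestChainRecordCounts:
    def test_histogram_conserves_chains_and_records(self, curated):
        counts, hist = chain_record_counts(curated)
        assert sum(hist.values()) == counts.size == 378
        assert counts.sum() == len(curated) == 439
        assert hist["2"] + hist["3"] + hist["4+"] == 43

    def test_singletons_only(self):
        rec = small_records([(f"p{i}", "A", "GLY", "SER", False, "")
                             for i in range(5)])
        _, hist = chain_record_counts(rec)
        assert hist == {"1": 5, "2": 0, "3": 0, "4+": 0}


class TestBackgroundFrequencies:
    def test_percent_file_autodetected(self, tmp_path):
        path = tmp_path / "bg.csv"
        path.write_text("\n".join(f"{aa},{100 * p}" for aa, p
                                  in UNIPROT_FREQUENCIES.items()))
        bg = BackgroundFrequencies.from_file(path)
        assert bg.p("LEU") == pytest.approx(0.0985)

    def test_bad_sum_rejected(self):
        freqs = {aa: 0.5 / 19 for aa in AA3 if aa != "GLY"}
        freqs["GLY"] = 0.2
        with pytest.raises(ValueError, match="sum"):
            BackgroundFrequencies(freqs)

    def test_must_cover_all_twenty(self):
        with pytest.raises(ValueError):
            BackgroundFrequencies({"GLY": 1.0})
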