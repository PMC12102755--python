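"""Reliability criteria, suspect flags and best-chain selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cisnonpro.filters import (FilterThresholds, apply_reliability_filter,
                               clash_overlaps, detect_vicinal_disulfide,
                               geometry_outliers, residue_quality,
                               select_best_chains, suspect_flags)
from cisnonpro.geometry import detect_cis_nonpro
from cisnonpro.model import (Atom, Chain, ChainAnnotation, LigandAtom,
                             Residue, ResidueAnnotation, Structure)
from cisnonpro.refdata import BOND_REFERENCE
from cisnonpro.synth import build_backbone
from conftest import make_chain


def good_annotation(residue, rscc=0.9, map_sigma=2.0, override=None):
    return ResidueAnnotation(residue.chain_id, residue.seq_number,
                             residue.insertion_code, rscc=rscc,
                             map_sigma=map_sigma, clash_override=override)


class TestGeometryOutliers:
    def test_reference_geometry_scores_zero(self, beta_chain):
        r = beta_chain.residues[4]
        z = geometry_outliers(r, beta_chain.residues[3], beta_chain.residues[5])
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_injected_five_esd_stretch_scores_five(self):
        chain = make_chain(bond_overrides={
            (4, "N-CA"): BOND_REFERENCE["N-CA"][0] + 5 * BOND_REFERENCE["N-CA"][1]})
        z = geometry_outliers(chain.residues[4], chain.residues[3],
                              chain.residues[5])
        assert z == pytest.approx(5.0, abs=1e-3)

    def test_incomplete_residue_returns_none(self):
        r = Residue("A", 1, "", "GLY", [Atom("CA", "C", [0, 0, 0])])
        assert geometry_outliers(r) is None


class TestClashOverlaps:
    def test_isolated_dipeptide_has_no_clash(self):
        chain = make_chain("AS")
        st = Structure("t", [chain], resolution=1.5)
        assert clash_overlaps(st, chain.residues[0]) == pytest.approx(0.0)

    def test_two_carbons_at_2p4_overlap_one_angstrom(self):
        r = Residue("A", 1, "", "ALA", [Atom("CB", "C", [0, 0, 0])])
        st = Structure("t", [Chain("A", [r])])
        st.ligand_atoms.append(LigandAtom("X", "LIG", 1,
                                          Atom("C1", "C", [2.4, 0, 0])))
        assert clash_overlaps(st, r) == pytest.approx(1.0)  # 1.7 + 1.7 - 2.4

    def test_annotation_override_replaces_computed_value(self):
        r = Residue("A", 1, "", "ALA", [Atom("CB", "C", [0, 0, 0])])
        st = Structure("t", [Chain("A", [r])])
        ann = ResidueAnnotation("A", 1, clash_override=0.62)
        assert clash_overlaps(st, r, annotation=ann) == pytest.approx(0.62)

    def test_hydrogen_bond_window_not_a_clash(self):
        r = Residue("A", 1, "", "SER", [Atom("OG", "O", [0, 0, 0])])
        st = Structure("t", [Chain("A", [r])])
        st.ligand_atoms.append(LigandAtom("X", "HOH", 1,
                                          Atom("O", "O", [2.9, 0, 0])))
        assert clash_overlaps(st, r) == pytest.approx(0.0)

    def test_disulfide_distance_not_a_clash(self):
        r = Residue("A", 1, "", "CYS", [Atom("SG", "S", [0, 0, 0])])
        other = Residue("A", 5, "", "CYS", [Atom("SG", "S", [2.05, 0, 0])])
        st = Structure("t", [Chain("A", [r, other])])
        assert clash_overlaps(st, r) == pytest.approx(0.0)


class TestResidueQuality:
    def _clean_structure(self):
        chain = make_chain()
        return chain, Structure("t", [chain], resolution=1.5)

    @pytest.mark.parametrize("kwargs,expected_failure", [
        (dict(b=45.0), "max_backbone_b"),
        (dict(rscc=0.65), "min_rscc"),
        (dict(map_sigma=1.0), "min_map_sigma"),
        (dict(override=0.5), "clash_overlap"),
    ])
    def test_threshold_violations_named(self, kwargs, expected_failure):
        chain, struct = self._clean_structure()
        r = chain.residues[4]
        if "b" in kwargs:
            for a in r.atoms:
                a.b_factor = kwargs["b"]
        ann = good_annotation(r, rscc=kwargs.get("rscc", 0.9),
                              map_sigma=kwargs.get("map_sigma", 2.0),
                              override=kwargs.get("override"))
        report = residue_quality(r, struct, ann,
                                 prev_residue=chain.residues[3],
                                 next_residue=chain.residues[5])
        assert expected_failure in report.failures

    def test_values_exactly_at_thresholds_pass(self):
        chain, struct = self._clean_structure()
        r = chain.residues[4]
        for a in r.atoms:
            a.b_factor = 40.0
        ann = good_annotation(r, rscc=0.7, map_sigma=1.2, override=0.49)
        report = residue_quality(r, struct, ann,
                                 prev_residue=chain.residues[3],
                                 next_residue=chain.residues[5])
        assert report.passed, report.failures

    def test_strict_mode_fails_missing_density(self):
        chain, struct = self._clean_structure()
        r = chain.residues[4]
        strict = residue_quality(r, struct, annotation=None, strict=True)
        relaxed = residue_quality(r, struct, annotation=None, strict=False)
        assert "missing_density" in strict.failures and not strict.passed
        assert relaxed.passed
        assert "min_rscc" in relaxed.not_evaluated


class TestVicinalDisulfide:
    def _cys_cys(self, sg_distance):
        chain = make_chain("ACCRAT", cis_bond=1)
        for i, res in enumerate(chain.residues[1:3], start=1):
            ca = res.atom("CA").position
            offset = np.array([0.0, 0.0, 1.8]) if i == 1 else \
                np.array([0.0, sg_distance, 1.8])
            base = chain.residues[1].atom("CA").position
            res.atoms.append(Atom("SG", "S", base + offset))
        return chain

    def test_bonded_pair_detected(self):
        from cisnonpro.model import CisNonProRecord
        chain = self._cys_cys(2.05)
        st = Structure("t", [chain], resolution=1.5)
        rec = CisNonProRecord("t", "A", 2, "CYS", 3, "CYS")
        flag, note = detect_vicinal_disulfide(rec, st)
        assert flag and "2.05" in note

    def test_distant_pair_not_flagged(self):
        from cisnonpro.model import CisNonProRecord
        st = Structure("t", [self._cys_cys(3.5)], resolution=1.5)
        assert not detect_vicinal_disulfide(
            CisNonProRecord("t", "A", 2, "CYS", 3, "CYS"), st)[0]

    def test_wrong_types_and_missing_sg(self):
        from cisnonpro.model import CisNonProRecord
        chain = make_chain("ASCRAT", cis_bond=1)
        st = Structure("t", [chain], resolution=1.5)
        assert not detect_vicinal_disulfide(
            CisNonProRecord("t", "A", 2, "SER", 3, "CYS"), st)[0]
        chain2 = make_chain("ACCRAT", cis_bond=1)  # Cys without SG atoms
        st2 = Structure("t", [chain2], resolution=1.5)
        flag, note = detect_vicinal_disulfide(
            CisNonProRecord("t", "A", 2, "CYS", 3, "CYS"), st2)
        assert not flag and note == "no SG"


class TestSuspectFlags:
    def test_terminal_cis_flagged(self):
        st = Structure("t", [make_chain("ASERAT", cis_bond=0)], resolution=1.5)
        records, _ = detect_cis_nonpro(st)
        flags = suspect_flags(records[0], st, records)
        assert flags.chain_terminal

    def test_tandem_cis_flagged_on_both(self):
        n = 12
        phi = [-120.0] * n
        psi = [130.0] * n
        omega = [180.0] * (n - 1)
        omega[5] = omega[6] = 0.0
        phi[6] = phi[7] = -90.0
        st = Structure("t", [build_backbone("ASERATLKVDAS", phi, psi, omega)],
                       resolution=1.5)
        records, _ = detect_cis_nonpro(st)
        assert len(records) == 2
        for rec in records:
            assert suspect_flags(rec, st, records).tandem_cis

    def test_high_b_window_marks_disordered_context(self):
        chain = make_chain(cis_bond=4,
                           b_factors=[15] * 3 + [80] + [15] * 6)
        st = Structure("t", [chain], resolution=1.5)
        records, _ = detect_cis_nonpro(st)
        assert suspect_flags(records[0], st, records).disordered_context

    def test_homodimer_with_trans_sister_chain_inconsistent(self):
        seq = "ASERATLKVD"
        cis_chain = make_chain(seq, cis_bond=4, chain_id="A")
        trans_chain = make_chain(seq, cis_bond=None, chain_id="B")
        for r in trans_chain.residues:
            for a in r.atoms:
                a.position = a.position + np.array([50.0, 0, 0])
        st = Structure("t", [cis_chain, trans_chain], resolution=1.5)
        records, _ = detect_cis_nonpro(st)
        (rec,) = records
        assert suspect_flags(rec, st, records).cross_chain_inconsistent

    def test_gly_flagged_for_extra_scrutiny(self):
        st = Structure("t", [make_chain("ASERGTLKVD", cis_bond=4)], resolution=1.5)
        records, _ = detect_cis_nonpro(st)
        assert suspect_flags(records[0], st, records).contains_gly


@pytest.fixture(scope="module")
def shared_case():
    """Detected records + baseline kept set for the monotonicity property."""
    import copy

    from cisnonpro.model import select_conformer
    from cisnonpro.synth import generate_case, standard_scenario
    case = generate_case(standard_scenario(seed=7, n_chains=26))
    structures = {k: select_conformer(s) for k, s in case.structures.items()}
    all_records = []
    for stc in structures.values():
        recs, _ = detect_cis_nonpro(stc)
        all_records.extend(recs)
    kept, _ = apply_reliability_filter(
        copy.deepcopy(all_records), structures, case.annotations)
    baseline = {(r.pdb, r.res1) for r in kept}
    return all_records, structures, case.annotations, baseline


class TestApplyFilter:
    def test_clean_plant_kept_and_decoy_rejected(self, benchmark_case,
                                                 benchmark_result):
        kept, rejected, counters = benchmark_result
        truth = benchmark_case.truth
        clean = truth[truth.kind == "genuine_cis_nonpro"]
        assert set(zip(kept.pdb, kept.res1.astype(int))) == \
            set(zip(clean.pdb, clean.res1.astype(int)))
        assert counters["rejected"] == len(truth) - len(clean)
        assert all(r for r in rejected.reasons)

    def test_rejection_reasons_within_vocabulary(self, benchmark_result):
        from cisnonpro.filters import CRITERIA
        _, rejected, _ = benchmark_result
        for reasons in rejected.reasons:
            assert set(reasons.split(";")) <= set(CRITERIA)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        b=st.floats(1.0, 3.0), rscc=st.floats(0.3, 1.0),
        sigma=st.floats(0.3, 1.0), z=st.floats(1.0, 3.0),
        clash=st.floats(1.0, 3.0),
    )
    def test_relaxing_thresholds_never_shrinks_kept_set(
            self, shared_case, b, rscc, sigma, z, clash):
        records, structures, annotations, baseline_kept = shared_case
        relaxed = FilterThresholds(
            max_backbone_b=40.0 * b, min_rscc=0.7 * rscc,
            min_map_sigma=1.2 * sigma, max_geometry_z=4.0 * z,
            clash_overlap=0.5 * clash)
        import copy
        kept, _ = apply_reliability_filter(
            copy.deepcopy(records), structures, annotations, relaxed)
        kept_keys = {(r.pdb, r.res1) for r in kept}
        assert baseline_kept <= kept_keys



class TestSelectBestChains:
    def _ann(self, pdb, res, mp, cluster="c1"):
        return ChainAnnotation(pdb, "A", resolution=res, molprobity_score=mp,
                               cluster_id=cluster)

    def test_best_average_wins(self):
        first = self._ann("1aaa", 1.5, 1.1)   # avg 1.30
        second = self._ann("1bbb", 1.9, 0.9)  # avg 1.40
        assert select_best_chains([first, second]) == [first]

    def test_singleton_cluster_kept(self):
        only = self._ann("1ccc", 1.8, 1.5)
        assert select_best_chains([only]) == [only]

    def test_cluster_at_resolution_cutoff_omitted(self):
        bad = [self._ann("1ddd", 2.0, 0.5), self._ann("1eee", 2.4, 0.5)]
        assert select_best_chains(bad) == []

    def test_tie_breaks_lexicographically(self):
        a = self._ann("1aaa", 1.5, 1.1)
        b = self._ann("1bbb", 1.1, 1.5)
        assert select_best_chains([b, a]) == [a]
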