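"""Coordinate parsing, conformer selection and sidecar-table round trips."""

import numpy as np
import pandas as pd
import pytest

from cisnonpro.model import (Atom, CisNonProRecord, ParseError, Residue,
                             Structure, frame_to_records, read_record_table,
                             read_residue_annotations, read_structure,
                             records_to_frame, select_conformer, write_pdb,
                             write_record_table)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      5  CA  GLY A   2       4.000   2.800   0.000  1.00 11.00           C
ATOM      6  C   GLY A   2       5.500   2.700   0.100  1.00 11.00           C
ATOM      7  N   SER A   3       6.200   3.800   0.150  1.00 12.00           N
ATOM      8  CA  SER A   3       7.650   3.850   0.200  1.00 12.00           C
ATOM      9  C   SER A   3       8.250   5.250   0.250  1.00 12.00           C
END
"""

MSE_PDB = """\
HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00 10.00           N
HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00 10.00           C
HETATM    3  C   MSE A   1       2.009   1.420   0.000  1.00 10.00           C
HETATM    4 SE   MSE A   1       3.000  -1.500   1.000  1.00 15.00          SE
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      6  CA  GLY A   2       4.000   2.800   0.000  1.00 11.00           C
ATOM      7  C   GLY A   2       5.500   2.700   0.100  1.00 11.00           C
END
"""


class TestReadStructure:
    def test_minimal_three_residue_file(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert len(st.chains) == 1
        assert len(st.chains[0].residues) == 3
        assert [r.aa_type for r in st.chains[0].residues] == ["ALA", "GLY", "SER"]

    def test_selenomethionine_promoted_to_met(self, tmp_path):
        p = tmp_path / "mse.pdb"
        p.write_text(MSE_PDB)
        st = read_structure(p)
        res = st.chains[0].residues[0]
        assert res.aa_type == "MET"
        assert res.atom("SD") is not None  # SE renamed to the Met atom name

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ParseError):
            read_structure(tmp_path / "absent.pdb")

    def test_no_protein_raises(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                     "  1.00 10.00           O\nEND\n")
        with pytest.raises(ParseError):
            read_structure(p)


class TestWriterRoundTrip:
    def test_coordinates_survive_to_pdb_precision(self, tmp_path, cis_structure):
        path = tmp_path / "rt.pdb"
        write_pdb(cis_structure, path)
        back = read_structure(path)
        assert back.resolution == pytest.approx(1.5)
        orig = cis_structure.chains[0].residues
        rt = back.chains[0].residues
        assert len(orig) == len(rt)
        for a, b in zip(orig, rt):
            assert a.aa_type == b.aa_type
            assert {x.name for x in a.atoms} == {x.name for x in b.atoms}
            for atom in a.atoms:
                other = b.atom(atom.name)
                assert np.abs(atom.position - other.position).max() <= 1.1e-3
                assert atom.b_factor == pytest.approx(other.b_factor, abs=5e-3)


class TestSelectConformer:
    def _residue_with_altlocs(self, occ_a, occ_b):
        return Residue("A", 1, "", "SER", [
            Atom("CA", "C", [0, 0, 0], 10, occ_a, "A"),
            Atom("CA", "C", [1, 0, 0], 12, occ_b, "B"),
        ])

    def test_highest_occupancy_wins(self):
        st = Structure("t", [__import__("cisnonpro").model.Chain(
            "A", [self._residue_with_altlocs(0.6, 0.4)])])
        out = select_conformer(st)
        (atom,) = out.chains[0].residues[0].atoms
        assert atom.position[0] == 0 and atom.altloc == ""

    def test_tie_breaks_alphabetically(self):
        st = Structure("t", [__import__("cisnonpro").model.Chain(
            "A", [self._residue_with_altlocs(0.5, 0.5)])])
        (atom,) = select_conformer(st).chains[0].residues[0].atoms
        assert atom.position[0] == 0  # altloc A retained

    def test_idempotent_and_identity_without_altlocs(self, cis_structure):
        once = select_conformer(cis_structure)
        twice = select_conformer(once)
        for c1, c2 in zip(once.chains, twice.chains):
            for r1, r2 in zip(c1.residues, c2.residues):
                assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]


class TestResidueAnnotations:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("chain,seq_number,insertion_code,rscc,map_sigma,clash_override\n"
                     "A,42,,0.81,2.3,\n")
        (ann,) = read_residue_annotations(p)
        assert ann.key == ("A", 42, "")
        assert ann.rscc == pytest.approx(0.81)
        assert ann.map_sigma == pytest.approx(2.3)
        assert ann.clash_override is None

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("chain,seq_number,rscc,map_sigma\n")
        assert read_residue_annotations(p) == []

    @pytest.mark.parametrize("body,match", [
        ("A,42,1.2,2.3\n", "rscc"),                       # out-of-range rscc
        ("A,42,0.8,2.3\nA,42,0.9,2.0\n", "duplicate"),    # duplicate key
        ("A,42,abc,2.3\n", "malformed"),                  # malformed number
    ])
    def test_rejects_bad_rows(self, tmp_path, body, match):
        p = tmp_path / "ann.csv"
        p.write_text("chain,seq_number,rscc,map_sigma\n" + body)
        with pytest.raises(ParseError, match=match):
            read_residue_annotations(p)


class TestRecordTable:
    def _records(self):
        return [
            CisNonProRecord("1abc", "B", 7, "TRP", 8, "SER", resolution=1.3,
                            omega=3.2, in_cazy=True, cazy_family="GH18",
                            flags=["contains_gly"]),
            CisNonProRecord("1abc", "A", 42, "GLY", 43, "GLY", resolution=1.3,
                            omega=-4.1),
        ]

    @pytest.mark.parametrize("dialect", ["csv", "tsv"])
    def test_round_trip(self, tmp_path, dialect):
        path = tmp_path / f"rec.{dialect}"
        write_record_table(self._records(), path, dialect=dialect)
        back = frame_to_records(read_record_table(path))
        orig = sorted(self._records(), key=lambda r: (r.pdb, r.chain, r.res1))
        assert len(back) == 2
        for a, b in zip(orig, back):
            assert (a.pdb, a.chain, a.res1, a.aa1, a.res2, a.aa2) == \
                (b.pdb, b.chain, b.res1, b.aa1, b.res2, b.aa2)
            assert a.omega == pytest.approx(b.omega)
            assert a.in_cazy == b.in_cazy and a.flags == b.flags

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_record_table([], path)
        df = pd.read_csv(path)
        assert len(df) == 0 and "omega" in df.columns

    def test_rows_sorted_by_chain_then_residue(self, tmp_path):
        path = tmp_path / "sorted.csv"
        write_record_table(self._records(), path)
        df = pd.read_csv(path)
        assert list(df["chain"]) == ["A", "B"]

    def test_alias_mapping(self, tmp_path):
        path = tmp_path / "ext.csv"
        path.write_text("PDB code,Chain,Res1,AA1,Res2,AA2\n1xyz,A,5,GLY,6,SER\n")
        df = read_record_table(path, aliases={
            "PDB code": "pdb", "Chain": "chain", "Res1": "res1",
            "AA1": "aa1", "Res2": "res2", "AA2": "aa2"})
        assert list(df["pdb"]) == ["1xyz"]
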