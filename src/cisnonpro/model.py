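"""Hierarchical coordinate model and readers/writers for sidecar tables.

Coordinate files (PDB or mmCIF) are parsed with gemmi into a small
purpose-built hierarchy (:class:`Structure` / :class:`Chain` /
:class:`Residue` / :class:`Atom`) that keeps only what the pipeline needs:
positions, B-factors, occupancies and altlocs of standard amino-acid
residues, plus a flat ligand/water heavy-atom store used by the clash
filter.  Author residue numbering (with insertion codes) is the public key
throughout, because the curated-list tables identify residues that way.

Sidecar tables -- per-residue density annotations, chain-level annotations
(CAZy families, fold labels, homology clusters) and the curated record
table itself -- are plain CSV/TSV handled through pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .refdata import AA3

_STANDARD_AA = set(AA3) | {"UNK"}

#: canonical column order of the curated record table
RECORD_COLUMNS = [
    "pdb", "chain", "res1", "aa1", "res2", "aa2", "resolution",
    "n_cis_nonpro_in_chain", "in_cazy", "cazy_family", "fold_label",
    "molecule_name", "omega", "verdict", "flags", "notes",
]


class ParseError(ValueError):
    """Raised when a coordinate or annotation file cannot be interpreted."""


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with displacement and occupancy."""

    name: str
    element: str
    position: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.b_factor}")


@dataclass
class Residue:
    """A standard amino-acid residue keyed by author numbering."""

    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa_type not in _STANDARD_AA:
            raise ValueError(f"unknown residue type {self.aa_type!r}")
        seen = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in residue {self.key}")
            seen.add(key)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.seq_number}{self.insertion_code}".strip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class LigandAtom:
    """A non-protein heavy atom kept only for steric-clash checks."""

    chain_id: str
    res_name: str
    seq_number: int
    atom: Atom


@dataclass
class Structure:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    ligand_atoms: list[LigandAtom] = field(default_factory=list)
    n_dropped_residues: int = 0

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def find_residue(self, chain_id: str, seq_number: int, icode: str = "") -> Residue | None:
        ch = self.chain(chain_id)
        if ch is None:
            return None
        for r in ch.residues:
            if r.seq_number == seq_number and r.insertion_code == icode:
                return r
        return None


@dataclass
class ResidueAnnotation:
    """Externally computed density metrics for one residue.

    rscc is the real-space correlation coefficient between model and map;
    map_sigma the 2mFo-DFc map value at the atom positions in sigma units;
    clash_override, when present, supersedes the built-in heavy-atom clash
    estimate with an externally computed all-atom overlap.
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    rscc: float | None = None
    map_sigma: float | None = None
    clash_override: float | None = None

    def __post_init__(self) -> None:
        if self.rscc is not None and not -1.0 <= self.rscc <= 1.0:
            raise ValueError(f"rscc {self.rscc} outside [-1, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class ChainAnnotation:
    """Chain-level survey metadata consumed (not computed) by the pipeline."""

    pdb: str
    chain_id: str
    cazy_families: list[str] = field(default_factory=list)
    molecule_name: str = ""
    fold_label: str = ""
    cluster_id: str = ""
    molprobity_score: float | None = None
    resolution: float | None = None

    def __post_init__(self) -> None:
        if any(not f for f in self.cazy_families):
            raise ValueError("empty CAZy family label")

    @property
    def key(self) -> tuple[str, str]:
        return (self.pdb, self.chain_id)

    @property
    def in_cazy(self) -> bool:
        return len(self.cazy_families) > 0


@dataclass
class CisNonProRecord:
    """One curated-list row: a cis peptide bond preceding a non-Pro residue."""

    pdb: str
    chain: str
    res1: int
    aa1: str
    res2: int
    aa2: str
    icode1: str = ""
    icode2: str = ""
    resolution: float | None = None
    n_cis_nonpro_in_chain: int = 1
    in_cazy: bool = False
    cazy_family: str = ""
    fold_label: str = ""
    molecule_name: str = ""
    omega: float | None = None
    verdict: str = ""
    flags: list[str] = field(default_factory=list)
    notes: str = ""

    @property
    def chain_key(self) -> tuple[str, str]:
        return (self.pdb, self.chain)


# ---------------------------------------------------------------------------
# coordinate reading


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the pipeline's structure model.

    Only the first model is used.  ATOM records of the 20 standard amino
    acids are retained; selenomethionine (MSE) is promoted to Met; every
    other HETATM, water and ligand goes to the flat ``ligand_atoms`` store
    so the clash filter can still see it.  Dropped polymer residues are
    counted in ``n_dropped_residues`` rather than silently discarded.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from None
    st.setup_entities()

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    out = Structure(entry_id=(st.name or path.stem).lower(), resolution=resolution)

    if len(st) == 0:
        raise ParseError(f"{path}: no model in file")
    model = st[0]
    n_protein = 0
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            name = gres.name
            if name == "MSE":
                name = "MET"
            if name in _STANDARD_AA:
                atoms = []
                for ga in gres:
                    if ga.is_hydrogen():
                        continue
                    atoms.append(Atom(
                        name="SD" if (gres.name == "MSE" and ga.name == "SE") else ga.name,
                        element=ga.element.name.upper(),
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        b_factor=ga.b_iso,
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=ga.altloc.strip("\x00") if ga.altloc else "",
                    ))
                chain.residues.append(Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    aa_type=name,
                    atoms=atoms,
                ))
                n_protein += 1
            else:
                is_polymer_aa = gres.name not in ("HOH", "DOD") and len(gres.name) == 3 and \
                    gemmi.find_tabulated_residue(gres.name) is not None and \
                    gemmi.find_tabulated_residue(gres.name).is_amino_acid()
                if is_polymer_aa:
                    out.n_dropped_residues += 1
                for ga in gres:
                    if ga.is_hydrogen():
                        continue
                    out.ligand_atoms.append(LigandAtom(
                        chain_id=gchain.name, res_name=gres.name,
                        seq_number=gres.seqid.num,
                        atom=Atom(name=ga.name, element=ga.element.name.upper(),
                                  position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                  b_factor=ga.b_iso,
                                  occupancy=min(max(ga.occ, 0.0), 1.0)),
                    ))
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            out.chains.append(chain)
    if n_protein == 0:
        raise ParseError(f"{path}: no protein residues")
    return out


def select_conformer(s: Structure) -> Structure:
    """Collapse alternate conformations: per residue keep, for each atom
    name, the altloc with the highest occupancy (ties broken alphabetically
    by altloc label).  Idempotent; atoms without altlocs pass through."""
    new_chains = []
    for ch in s.chains:
        new_res = []
        for r in ch.residues:
            best: dict[str, Atom] = {}
            for a in sorted(r.atoms, key=lambda a: (a.name, a.altloc)):
                cur = best.get(a.name)
                if cur is None or a.occupancy > cur.occupancy:
                    best[a.name] = a
            atoms = [replace(best[n], altloc="") for n in sorted(best)]
            new_res.append(Residue(r.chain_id, r.seq_number, r.insertion_code,
                                   r.aa_type, atoms))
        new_chains.append(Chain(ch.chain_id, new_res))
    return Structure(s.entry_id, new_chains, s.resolution, list(s.ligand_atoms),
                     s.n_dropped_residues)


# ---------------------------------------------------------------------------
# coordinate writing (deterministic PDB output for synthetic structures)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as a PDB v3.3 file with deterministic formatting."""
    lines = []
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {s.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for ch in s.chains:
        for r in ch.residues:
            for a in r.atoms:
                lines.append(_pdb_atom_line("ATOM", serial, a, r.aa_type,
                                            ch.chain_id, r.seq_number,
                                            r.insertion_code))
                serial += 1
        last = ch.residues[-1]
        lines.append(f"TER   {serial:>5}      {last.aa_type:>3} "
                     f"{ch.chain_id:1}{last.seq_number:>4}{last.insertion_code or ' '}")
        serial += 1
    for la in s.ligand_atoms:
        lines.append(_pdb_atom_line("HETATM", serial, la.atom, la.res_name,
                                    la.chain_id, la.seq_number, ""))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom_line(rec: str, serial: int, a: Atom, res_name: str,
                   chain_id: str, seq: int, icode: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
    x, y, z = a.position
    return (f"{rec:<6}{serial:>5} {name}{a.altloc or ' '}{res_name:>3} "
            f"{chain_id:1}{seq:>4}{icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2}")


# ---------------------------------------------------------------------------
# annotation tables


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_residue_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read the per-residue density-metric table.

    Required columns: chain, seq_number; optional: insertion_code, rscc,
    map_sigma, clash_override.  Empty cells become absent values, never
    zeros.  Duplicate residue keys and malformed numbers are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"chain", "seq_number"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: list[ResidueAnnotation] = []
    seen = set()
    for i, row in df.iterrows():
        def num(col: str) -> float | None:
            val = str(row[col]).strip() if col in df.columns else ""
            if val == "":
                return None
            try:
                return float(val)
            except ValueError:
                raise ParseError(f"{path}: row {i}: malformed number {val!r} in {col}")
        try:
            ann = ResidueAnnotation(
                chain_id=str(row["chain"]).strip(),
                seq_number=int(str(row["seq_number"]).strip()),
                insertion_code=str(row.get("insertion_code", "")).strip(),
                rscc=num("rscc"),
                map_sigma=num("map_sigma"),
                clash_override=num("clash_override"),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
        if ann.key in seen:
            raise ParseError(f"{path}: duplicate residue key {ann.key}")
        seen.add(ann.key)
        out.append(ann)
    return out


def read_chain_annotations(path: str | Path) -> list[ChainAnnotation]:
    """Read the chain-level table (CAZy families ';'-separated, may be empty)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = {"pdb", "chain"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        fams = [f for f in str(row.get("cazy_families", "")).split(";") if f.strip()]
        def opt_float(col: str) -> float | None:
            v = str(row.get(col, "")).strip()
            return float(v) if v else None
        out.append(ChainAnnotation(
            pdb=str(row["pdb"]).strip().lower(),
            chain_id=str(row["chain"]).strip(),
            cazy_families=[f.strip() for f in fams],
            molecule_name=str(row.get("molecule_name", "")).strip(),
            fold_label=str(row.get("fold_label", "")).strip(),
            cluster_id=str(row.get("cluster_id", "")).strip(),
            molprobity_score=opt_float("molprobity_score"),
            resolution=opt_float("resolution"),
        ))
    return out


# ---------------------------------------------------------------------------
# curated record table


def _fmt_res(num: int, icode: str) -> str:
    return f"{num}{icode}".strip()


def _split_res(text: str) -> tuple[int, str]:
    text = str(text).strip()
    digits = ""
    i = 0
    if text.startswith("-"):
        digits, i = "-", 1
    while i < len(text) and text[i].isdigit():
        digits += text[i]
        i += 1
    return int(digits), text[i:].strip()


def records_to_frame(records: list[CisNonProRecord]) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda r: (r.pdb, r.chain, r.res1, r.icode1)):
        rows.append({
            "pdb": r.pdb, "chain": r.chain,
            "res1": _fmt_res(r.res1, r.icode1), "aa1": r.aa1,
            "res2": _fmt_res(r.res2, r.icode2), "aa2": r.aa2,
            "resolution": r.resolution,
            "n_cis_nonpro_in_chain": r.n_cis_nonpro_in_chain,
            "in_cazy": bool(r.in_cazy), "cazy_family": r.cazy_family,
            "fold_label": r.fold_label, "molecule_name": r.molecule_name,
            "omega": r.omega, "verdict": r.verdict,
            "flags": ";".join(r.flags), "notes": r.notes,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CisNonProRecord]:
    records = []
    for _, row in df.iterrows():
        res1, ic1 = _split_res(row["res1"])
        res2, ic2 = _split_res(row["res2"])

        def opt(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return float(v)

        def text(col):
            v = row.get(col, "")
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return ""
            return str(v)

        flags = [f for f in text("flags").split(";") if f]
        records.append(CisNonProRecord(
            pdb=str(row["pdb"]).lower(), chain=str(row["chain"]),
            res1=res1, icode1=ic1, aa1=str(row["aa1"]).upper(),
            res2=res2, icode2=ic2, aa2=str(row["aa2"]).upper(),
            resolution=opt("resolution"),
            n_cis_nonpro_in_chain=int(row.get("n_cis_nonpro_in_chain", 1)),
            in_cazy=str(row.get("in_cazy", "False")).strip().lower() in ("true", "1", "yes"),
            cazy_family=text("cazy_family"),
            fold_label=text("fold_label"),
            molecule_name=text("molecule_name"),
            omega=opt("omega"),
            verdict=text("verdict"),
            flags=flags, notes=text("notes"),
        ))
    return records


def write_record_table(records: list[CisNonProRecord], path: str | Path,
                       dialect: str = "csv") -> None:
    """Write the curated-list table, sorted by (pdb, chain, first residue)."""
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = records_to_frame(records)
    df.to_csv(path, sep="," if dialect == "csv" else "\t", index=False)


def read_record_table(path: str | Path,
                      aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a curated-list table, mapping alternative column headers through
    ``aliases`` (external header -> canonical name) before validation."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if aliases:
        df = df.rename(columns=aliases)
    missing = {"pdb", "chain", "res1", "aa1", "res2", "aa2"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: record table missing columns {sorted(missing)}")
    return df
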