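"""Backbone dihedrals, chain-break detection and cis/trans classification.

The omega dihedral CA(i)-C(i)-N(i+1)-CA(i+1) describes peptide-bond
isomerism: near 180 deg is trans, near 0 deg is cis, anything far from both
is "twisted" and treated as its own label rather than lumped with cis.  A
cis bond whose following residue is not proline is the rare cis-nonPro
class this package curates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Chain, ChainAnnotation, CisNonProRecord, Residue, Structure

#: maximum C(i)-N(i+1) distance for a covalent peptide link, Angstrom
PEPTIDE_BOND_CUTOFF = 2.5


class DegenerateGeometryError(ValueError):
    """Torsion requested for collinear or coincident points."""


def wrap_degrees(angle) -> np.ndarray | float:
    """Wrap an angle (degrees) into the interval (-180, 180]."""
    wrapped = -np.remainder(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    return float(wrapped) if np.isscalar(angle) or np.ndim(angle) == 0 else wrapped


def circular_difference(a: float, b: float) -> float:
    """Unsigned circular separation of two angles in degrees, in [0, 180]."""
    return abs(wrap_degrees(a - b))


def torsion(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle of four points, degrees in (-180, 180].

    Looking along p2->p3, the angle is positive when p4 is rotated
    clockwise from p1.  Invariant under rigid-body motion; raises
    :class:`DegenerateGeometryError` for collinear/coincident input.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9:
        raise DegenerateGeometryError("central bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def classify_omega(omega: float, cis_halfwidth: float = 30.0,
                   trans_halfwidth: float = 30.0) -> str:
    """Label a peptide omega as cis, trans or twisted.

    cis iff |omega| <= cis_halfwidth; trans iff the circular distance from
    180 deg is <= trans_halfwidth; everything else is twisted.  With the
    default 30 deg half-widths (the convention of mainstream validation
    tools) the three labels partition the circle and boundary values fall
    in the closed cis/trans windows.
    """
    omega = wrap_degrees(omega)
    if abs(omega) <= cis_halfwidth:
        return "cis"
    if circular_difference(omega, 180.0) <= trans_halfwidth:
        return "trans"
    return "twisted"


@dataclass
class PeptideBond:
    """One backbone linkage between consecutive residues of a chain."""

    first: Residue
    second: Residue
    omega: float | None
    classification: str | None
    crosses_break: bool
    is_chain_terminal_link: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return self.first.key


def peptide_bonds(chain: Chain, cis_halfwidth: float = 30.0,
                  trans_halfwidth: float = 30.0) -> list[PeptideBond]:
    """Enumerate peptide linkages between consecutive residues.

    A pair is a real bond when both residues have complete backbones and
    the C(i)-N(i+1) distance is <= 2.5 A; otherwise the pair is emitted
    with ``crosses_break`` set and no omega, so breaks are data rather
    than silent gaps.  The first and last non-break linkage of each
    contiguous segment are flagged chain-terminal.
    """
    bonds: list[PeptideBond] = []
    for r1, r2 in zip(chain.residues, chain.residues[1:]):
        broken = True
        omega = None
        if r1.has_backbone() and r2.has_backbone():
            d = float(np.linalg.norm(r2.atom("N").position - r1.atom("C").position))
            if d <= PEPTIDE_BOND_CUTOFF:
                broken = False
                omega = torsion(r1.atom("CA").position, r1.atom("C").position,
                                r2.atom("N").position, r2.atom("CA").position)
        bonds.append(PeptideBond(
            first=r1, second=r2, omega=omega,
            classification=None if omega is None
            else classify_omega(omega, cis_halfwidth, trans_halfwidth),
            crosses_break=broken,
        ))
    # mark the first/last intact linkage of each contiguous segment
    segment: list[PeptideBond] = []
    for b in bonds + [None]:  # type: ignore[list-item]
        if b is not None and not b.crosses_break:
            segment.append(b)
        else:
            if segment:
                segment[0].is_chain_terminal_link = True
                segment[-1].is_chain_terminal_link = True
            segment = []
    return bonds


@dataclass
class BackboneDihedrals:
    """Per-residue phi/psi keyed by residue; absent at ends and breaks."""

    phi: dict[tuple[str, int, str], float]
    psi: dict[tuple[str, int, str], float]


def backbone_phi_psi(chain: Chain) -> BackboneDihedrals:
    """Compute phi(i) = C(i-1)-N(i)-CA(i)-C(i) and psi(i) =
    N(i)-CA(i)-C(i)-N(i+1), absent across chain breaks."""
    bonds = peptide_bonds(chain)
    linked = {(b.first.key, b.second.key) for b in bonds if not b.crosses_break}
    phi: dict = {}
    psi: dict = {}
    res = chain.residues
    for i, r in enumerate(res):
        if not r.has_backbone():
            continue
        if i > 0 and (res[i - 1].key, r.key) in linked:
            phi[r.key] = torsion(res[i - 1].atom("C").position, r.atom("N").position,
                                 r.atom("CA").position, r.atom("C").position)
        if i + 1 < len(res) and (r.key, res[i + 1].key) in linked:
            psi[r.key] = torsion(r.atom("N").position, r.atom("CA").position,
                                 r.atom("C").position, res[i + 1].atom("N").position)
    return BackboneDihedrals(phi=phi, psi=psi)


def detect_cis_nonpro(structure: Structure,
                      chain_annotations: dict[tuple[str, str], ChainAnnotation] | None = None,
                      cis_halfwidth: float = 30.0,
                      ) -> tuple[list[CisNonProRecord], dict]:
    """Find every cis peptide bond whose second residue is not proline.

    Returns the records plus a counter dict; cis-Pro bonds are counted
    separately (they are the common ~5% class, not curated here).  Records
    carry omega, both residue identities and the per-chain cis-nonPro
    count; CAZy/molecule metadata is attached when annotations are given.
    """
    chain_annotations = chain_annotations or {}
    counters = {"bonds": 0, "breaks": 0, "cis_pro": 0, "cis_nonpro": 0,
                "trans": 0, "twisted": 0}
    records: list[CisNonProRecord] = []
    for chain in structure.chains:
        chain_records: list[CisNonProRecord] = []
        for bond in peptide_bonds(chain, cis_halfwidth=cis_halfwidth):
            if bond.crosses_break:
                counters["breaks"] += 1
                continue
            counters["bonds"] += 1
            if bond.classification == "trans":
                counters["trans"] += 1
            elif bond.classification == "twisted":
                counters["twisted"] += 1
            elif bond.second.aa_type == "PRO":
                counters["cis_pro"] += 1
            else:
                counters["cis_nonpro"] += 1
                ann = chain_annotations.get((structure.entry_id, chain.chain_id))
                chain_records.append(CisNonProRecord(
                    pdb=structure.entry_id, chain=chain.chain_id,
                    res1=bond.first.seq_number, icode1=bond.first.insertion_code,
                    aa1=bond.first.aa_type,
                    res2=bond.second.seq_number, icode2=bond.second.insertion_code,
                    aa2=bond.second.aa_type,
                    resolution=structure.resolution,
                    omega=bond.omega,
                    in_cazy=ann.in_cazy if ann else False,
                    cazy_family=";".join(ann.cazy_families) if ann else "",
                    fold_label=ann.fold_label if ann else "",
                    molecule_name=ann.molecule_name if ann else "",
                ))
        for rec in chain_records:
            rec.n_cis_nonpro_in_chain = len(chain_records)
        records.extend(chain_records)
    return records, counters
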