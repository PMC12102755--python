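"""Residue-level reliability filters and suspect-pattern flags.

A cis-nonPro observation is only trusted when both flanking residues are
demonstrably well ordered: backbone B-factors at most 40 A^2, real-space
correlation at least 0.7, 2mFo-DFc map value at least 1.2 sigma, no
covalent-geometry outlier beyond 4 esd and no steric overlap of 0.5 A or
more.  Density metrics are consumed from annotation tables (they require
the experimental map); geometry and clashes are computed here, with an
annotation override available for externally computed all-atom clashes.

Beyond the five per-residue criteria, structural context patterns that have
historically always indicated misfit cis bonds are flagged: bonds at chain
ends, two-in-a-row cis-nonPro, partially disordered local loops, and bonds
whose equivalent in an identical sister chain is trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import classify_omega, peptide_bonds, torsion
from .model import ChainAnnotation, CisNonProRecord, Residue, ResidueAnnotation, Structure
from .refdata import ANGLE_REFERENCE, BOND_REFERENCE, VDW_RADII

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

#: reasons that reject a record regardless of per-residue metrics
FATAL_SUSPECT_FLAGS = ("chain_terminal", "tandem_cis")

CRITERIA = ("max_backbone_b", "min_rscc", "min_map_sigma", "max_geometry_z",
            "clash_overlap", "missing_density", "max_resolution",
            "chain_terminal", "tandem_cis", "incomplete")


@dataclass
class FilterThresholds:
    """The residue-level reliability cutoffs.

    Comparisons are strict as conventionally stated: a residue fails on
    B-factor > 40, RSCC < 0.7, map value < 1.2 sigma, geometry |z| > 4, or
    clash overlap >= 0.5 A, so a value exactly at threshold passes (except
    the clash, whose criterion is inclusive).
    """

    max_backbone_b: float = 40.0     # A^2, over N, CA, C, O, CB
    min_rscc: float = 0.7
    min_map_sigma: float = 1.2       # sigma units
    max_geometry_z: float = 4.0      # esd multiples
    clash_overlap: float = 0.5       # A, inclusive
    max_resolution: float = 2.0      # A, structures at/above are excluded

    def __post_init__(self) -> None:
        for name in ("max_backbone_b", "min_rscc", "min_map_sigma",
                     "max_geometry_z", "clash_overlap", "max_resolution"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QualityReport:
    residue_key: tuple[str, int, str]
    max_backbone_b: float | None = None
    rscc: float | None = None
    map_sigma: float | None = None
    worst_geometry_z: float | None = None
    worst_clash_overlap: float | None = None
    failures: list[str] = field(default_factory=list)
    not_evaluated: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


@dataclass
class SuspectFlags:
    chain_terminal: bool = False
    tandem_cis: bool = False
    disordered_context: bool = False
    cross_chain_inconsistent: bool = False
    contains_gly: bool = False
    vicinal_disulfide: bool = False

    def as_list(self) -> list[str]:
        return [name for name in ("chain_terminal", "tandem_cis",
                                  "disordered_context", "cross_chain_inconsistent",
                                  "contains_gly", "vicinal_disulfide")
                if getattr(self, name)]


# ---------------------------------------------------------------------------
# covalent geometry


def _angle(p1, p2, p3) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def geometry_outliers(residue: Residue, prev_residue: Residue | None = None,
                      next_residue: Residue | None = None) -> float | None:
    """Worst absolute z over backbone covalent bonds and angles.

    z = |observed - target| / esd against the shipped reference table;
    evaluated terms: N-CA, CA-C, C-O, CA-CB and C-N(next) bond lengths and
    the N-CA-C, CA-C-O, CA-C-N(next) and C(prev)-N-CA angles.  Returns
    None (caller flags the residue incomplete) when N, CA or C is missing.
    """
    if not residue.has_backbone():
        return None
    pos = {name: residue.atom(name).position
           for name in BACKBONE_ATOMS if residue.atom(name) is not None}
    zs: list[float] = []

    def bond_z(key: str, a, b) -> None:
        target, esd = BOND_REFERENCE[key]
        zs.append(abs(float(np.linalg.norm(a - b)) - target) / esd)

    def angle_z(key: str, a, b, c) -> None:
        target, esd = ANGLE_REFERENCE[key]
        zs.append(abs(_angle(a, b, c) - target) / esd)

    bond_z("N-CA", pos["N"], pos["CA"])
    bond_z("CA-C", pos["CA"], pos["C"])
    if "O" in pos:
        bond_z("C-O", pos["C"], pos["O"])
        angle_z("CA-C-O", pos["CA"], pos["C"], pos["O"])
    if "CB" in pos:
        bond_z("CA-CB", pos["CA"], pos["CB"])
    angle_z("N-CA-C", pos["N"], pos["CA"], pos["C"])
    if next_residue is not None and next_residue.atom("N") is not None:
        nxt = next_residue.atom("N").position
        if float(np.linalg.norm(nxt - pos["C"])) <= 2.5:
            bond_z("C-N+", pos["C"], nxt)
            angle_z("CA-C-N+", pos["CA"], pos["C"], nxt)
    if prev_residue is not None and prev_residue.atom("C") is not None:
        prv = prev_residue.atom("C").position
        if float(np.linalg.norm(pos["N"] - prv)) <= 2.5:
            angle_z("-C-N-CA", prv, pos["N"], pos["CA"])
    return max(zs)


# ---------------------------------------------------------------------------
# steric clashes (heavy-atom approximation of all-atom contact analysis)


class ClashContext:
    """Precomputed atom arrays + KD-tree for one conformer-selected structure."""

    def __init__(self, structure: Structure):
        positions = []
        meta = []  # (chain_id, seq_number, element, is_protein)
        for ch in structure.chains:
            for r in ch.residues:
                for a in r.atoms:
                    if a.element != "H":
                        positions.append(a.position)
                        meta.append((ch.chain_id, r.seq_number, a.element, True))
        for la in structure.ligand_atoms:
            if la.atom.element != "H":
                positions.append(la.atom.position)
                meta.append((la.chain_id, la.seq_number, la.atom.element, False))
        self.positions = np.asarray(positions) if positions else np.zeros((0, 3))
        self.meta = meta
        self.tree = cKDTree(self.positions) if len(positions) else None


def clash_overlaps(structure: Structure, residue: Residue,
                   annotation: ResidueAnnotation | None = None,
                   context: ClashContext | None = None) -> float:
    """Worst van der Waals overlap (A) of the residue's heavy atoms.

    overlap = r_vdw(a) + r_vdw(b) - d(a, b) over all heavy atoms within
    5 A, skipping near-bonded pairs (same or sequence-adjacent residue of
    the same chain, and S-S pairs at disulfide distance <= 2.5 A) and
    N/O...N/O pairs with d in [2.4, 3.2] A, which are treated as hydrogen
    bonds rather than clashes.  Returns 0 when nothing overlaps.  A
    ``clash_override`` on the annotation (an externally computed all-atom
    value) replaces the computed number entirely.
    """
    if annotation is not None and annotation.clash_override is not None:
        return annotation.clash_override
    ctx = context or ClashContext(structure)
    if ctx.tree is None:
        return 0.0
    worst = 0.0
    for a in residue.atoms:
        if a.element == "H":
            continue
        ra = VDW_RADII.get(a.element, 1.70)
        for j in ctx.tree.query_ball_point(a.position, r=5.0):
            chain_id, seq, element, is_protein = ctx.meta[j]
            if is_protein and chain_id == residue.chain_id and \
                    abs(seq - residue.seq_number) <= 1:
                continue  # same or adjacent residue: covalently connected region
            d = float(np.linalg.norm(ctx.positions[j] - a.position))
            if d < 1e-6:
                continue  # the atom itself
            if a.element in ("N", "O") and element in ("N", "O") and 2.4 <= d <= 3.2:
                continue  # donor-acceptor hydrogen bond
            if a.element == "S" and element == "S" and d <= 2.5:
                continue  # disulfide bond
            overlap = ra + VDW_RADII.get(element, 1.70) - d
            worst = max(worst, overlap)
    return worst


# ---------------------------------------------------------------------------
# per-residue verdict


def residue_quality(residue: Residue, structure: Structure,
                    annotation: ResidueAnnotation | None = None,
                    thresholds: FilterThresholds | None = None,
                    strict: bool = True,
                    prev_residue: Residue | None = None,
                    next_residue: Residue | None = None,
                    context: ClashContext | None = None) -> QualityReport:
    """Apply the five reliability criteria to one residue.

    Criteria whose inputs are absent are listed as not evaluated; in
    strict mode (the default) a missing density annotation is itself a
    failure ("missing_density") so that unverifiable residues are
    rejected rather than passed by default.
    """
    th = thresholds or FilterThresholds()
    report = QualityReport(residue_key=residue.key)
    b_values = [residue.atom(n).b_factor for n in BACKBONE_ATOMS
                if residue.atom(n) is not None]
    if b_values:
        report.max_backbone_b = max(b_values)
        if report.max_backbone_b > th.max_backbone_b:
            report.failures.append("max_backbone_b")
    if annotation is not None and annotation.rscc is not None:
        report.rscc = annotation.rscc
        if report.rscc < th.min_rscc:
            report.failures.append("min_rscc")
    else:
        report.not_evaluated.append("min_rscc")
    if annotation is not None and annotation.map_sigma is not None:
        report.map_sigma = annotation.map_sigma
        if report.map_sigma < th.min_map_sigma:
            report.failures.append("min_map_sigma")
    else:
        report.not_evaluated.append("min_map_sigma")
    if strict and ("min_rscc" in report.not_evaluated or
                   "min_map_sigma" in report.not_evaluated):
        report.failures.append("missing_density")
    z = geometry_outliers(residue, prev_residue, next_residue)
    if z is None:
        report.failures.append("incomplete")
        report.not_evaluated.append("max_geometry_z")
    else:
        report.worst_geometry_z = z
        if z > th.max_geometry_z:
            report.failures.append("max_geometry_z")
    report.worst_clash_overlap = clash_overlaps(structure, residue, annotation,
                                                context)
    if report.worst_clash_overlap >= th.clash_overlap:
        report.failures.append("clash_overlap")
    return report


# ---------------------------------------------------------------------------
# suspect patterns


def detect_vicinal_disulfide(record: CisNonProRecord,
                             structure: Structure) -> tuple[bool, str]:
    """True iff both residues are Cys with SG-SG at disulfide distance
    (<= 2.5 A).  Returns (flag, note); a missing SG yields (False, note)."""
    if record.aa1 != "CYS" or record.aa2 != "CYS":
        return False, ""
    r1 = structure.find_residue(record.chain, record.res1, record.icode1)
    r2 = structure.find_residue(record.chain, record.res2, record.icode2)
    if r1 is None or r2 is None:
        return False, "residues not found"
    sg1, sg2 = r1.atom("SG"), r2.atom("SG")
    if sg1 is None or sg2 is None:
        return False, "no SG"
    d = float(np.linalg.norm(sg1.position - sg2.position))
    return d <= 2.5, f"SG-SG {d:.2f} A"


def _chain_sequence_window(chain, index: int, halfwidth: int = 3) -> tuple[str, ...]:
    lo = max(0, index - halfwidth)
    hi = min(len(chain.residues), index + 2 + halfwidth)
    return tuple(r.aa_type for r in chain.residues[lo:hi])


def suspect_flags(record: CisNonProRecord, structure: Structure,
                  all_records: list[CisNonProRecord] | None = None,
                  thresholds: FilterThresholds | None = None) -> SuspectFlags:
    """Structural-context flags for one detected cis-nonPro bond.

    chain_terminal and tandem_cis mark the two situations that have always
    proven to be misfits; disordered_context marks bonds sitting in a
    +-2-residue window with high-B or incomplete residues;
    cross_chain_inconsistent marks bonds whose equivalent (same local
    sequence, +-3 residues) in a sister chain of the same structure is
    trans; contains_gly marks bonds needing extra scrutiny (no CB on Gly
    means less density to cross-check); vicinal_disulfide marks the
    genuine Cys-cis-Cys adjacent-disulfide motif.
    """
    th = thresholds or FilterThresholds()
    all_records = all_records if all_records is not None else [record]
    flags = SuspectFlags()
    flags.contains_gly = "GLY" in (record.aa1, record.aa2)
    flags.vicinal_disulfide = detect_vicinal_disulfide(record, structure)[0]

    chain = structure.chain(record.chain)
    if chain is None:
        return flags
    idx = next((i for i, r in enumerate(chain.residues)
                if (r.seq_number, r.insertion_code) == (record.res1, record.icode1)),
               None)
    if idx is None:
        return flags

    for bond in peptide_bonds(chain):
        if bond.first.key == (record.chain, record.res1, record.icode1):
            flags.chain_terminal = bond.is_chain_terminal_link
            break

    for other in all_records:
        if other is record or other.pdb != record.pdb or other.chain != record.chain:
            continue
        if (other.res1, other.icode1) == (record.res2, record.icode2) or \
                (other.res2, other.icode2) == (record.res1, record.icode1):
            flags.tandem_cis = True

    lo, hi = max(0, idx - 2), min(len(chain.residues), idx + 4)
    for r in chain.residues[lo:hi]:
        if not r.has_backbone():
            flags.disordered_context = True
            break
        worst_b = max(r.atom(n).b_factor for n in BACKBONE_ATOMS
                      if r.atom(n) is not None)
        if worst_b > th.max_backbone_b:
            flags.disordered_context = True
            break

    window = _chain_sequence_window(chain, idx)
    offset = idx - max(0, idx - 3)
    for other_chain in structure.chains:
        if other_chain.chain_id == chain.chain_id:
            continue
        seq = [r.aa_type for r in other_chain.residues]
        for start in range(0, len(seq) - len(window) + 1):
            if tuple(seq[start:start + len(window)]) != window:
                continue
            r1 = other_chain.residues[start + offset]
            r2 = other_chain.residues[start + offset + 1]
            if r1.has_backbone() and r2.has_backbone():
                d = float(np.linalg.norm(r2.atom("N").position - r1.atom("C").position))
                if d <= 2.5:
                    omega = torsion(r1.atom("CA").position, r1.atom("C").position,
                                    r2.atom("N").position, r2.atom("CA").position)
                    if classify_omega(omega) == "trans":
                        flags.cross_chain_inconsistent = True
            break
    return flags


# ---------------------------------------------------------------------------
# record-level filtering


def apply_reliability_filter(
    records: list[CisNonProRecord],
    structures: dict[str, Structure],
    annotations: dict[str, dict[tuple[str, int, str], ResidueAnnotation]] | None = None,
    thresholds: FilterThresholds | None = None,
    strict: bool = True,
) -> tuple[list[CisNonProRecord], list[tuple[CisNonProRecord, list[str]]]]:
    """Keep a record iff both flanking residues pass every reliability
    criterion, the structure's resolution is below the cutoff, and no
    fatal suspect pattern (chain-terminal or tandem cis) is present.

    Every rejection carries a machine-readable reason list.  Kept records
    get verdict "genuine" and their suspect flags recorded; rejected ones
    get verdict "rejected".
    """
    th = thresholds or FilterThresholds()
    annotations = annotations or {}
    kept: list[CisNonProRecord] = []
    rejected: list[tuple[CisNonProRecord, list[str]]] = []
    contexts: dict[str, ClashContext] = {}
    for rec in records:
        structure = structures[rec.pdb]
        ctx = contexts.setdefault(rec.pdb, ClashContext(structure))
        res_anns = annotations.get(rec.pdb, {})
        reasons: list[str] = []
        if structure.resolution is None:
            if strict:
                reasons.append("max_resolution")
        elif not structure.resolution < th.max_resolution:
            reasons.append("max_resolution")
        chain = structure.chain(rec.chain)
        residues = chain.residues if chain else []
        for seq, icode in ((rec.res1, rec.icode1), (rec.res2, rec.icode2)):
            idx = next((i for i, r in enumerate(residues)
                        if (r.seq_number, r.insertion_code) == (seq, icode)), None)
            if idx is None:
                reasons.append("incomplete")
                continue
            r = residues[idx]
            report = residue_quality(
                r, structure,
                annotation=res_anns.get(r.key),
                thresholds=th, strict=strict,
                prev_residue=residues[idx - 1] if idx > 0 else None,
                next_residue=residues[idx + 1] if idx + 1 < len(residues) else None,
                context=ctx,
            )
            reasons.extend(f for f in report.failures if f not in reasons)
        flags = suspect_flags(rec, structure, records, th)
        rec.flags = flags.as_list()
        for fatal in FATAL_SUSPECT_FLAGS:
            if getattr(flags, fatal) and fatal not in reasons:
                reasons.append(fatal)
        if reasons:
            rec.verdict = "rejected"
            rejected.append((rec, reasons))
        else:
            rec.verdict = "genuine"
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# dataset construction


def select_best_chains(chain_annotations: list[ChainAnnotation],
                       max_resolution: float = 2.0) -> list[ChainAnnotation]:
    """Pick the best chain of each homology cluster: the one minimising the
    average of resolution and composite model-quality score, after
    excluding chains at or above the resolution cutoff.  Ties break on the
    lexicographic chain key; clusters with no eligible chain are omitted."""
    clusters: dict[str, list[ChainAnnotation]] = {}
    for ann in chain_annotations:
        if ann.resolution is None or ann.molprobity_score is None:
            raise ValueError(f"chain {ann.key}: resolution and molprobity_score required")
        if ann.resolution < max_resolution:
            clusters.setdefault(ann.cluster_id, []).append(ann)
    best = []
    for cluster_id in sorted(clusters):
        members = clusters[cluster_id]
        members.sort(key=lambda a: ((a.resolution + a.molprobity_score) / 2.0, a.key))
        best.append(members[0])
    return best
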