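"""Synthetic structures and survey samples with known ground truth.

Backbones are built forward from internal coordinates (the natural
extension reference frame): every bond length, bond angle and dihedral is
imposed exactly, so re-measuring phi/psi/omega recovers the targets to
numerical precision and an undistorted build scores zero on the
covalent-geometry filter by construction (the builder and the filter share
one reference table).

Scenario generation plants cis-nonPro bonds at known positions and
realises corruption directives that emulate how misfit cis bonds present
in real crystal structures: locally disordered B-factors with weak density
metrics, a stretched covalent bond, an injected steric clash, and the
chain-terminal / two-in-a-row placements that are diagnostic of misfits.
Density metrics (RSCC, map sigma) cannot be computed without experimental
maps, so they are simulated as draws correlated with the B-factor profile,
with ranges straddling the filter thresholds.

Survey sampling generates chain/record sets with configurable CAZy
enrichment folds for calibrating the enrichment statistics under null and
effect conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Atom, Chain, LigandAtom, Residue, ResidueAnnotation, Structure
from .refdata import AA1_TO_3, ANGLE_REFERENCE, BOND_REFERENCE, UNIPROT_FREQUENCIES
from .survey import BackgroundFrequencies


@dataclass
class GeometryParams:
    """Covalent geometry targets used by the builder; defaults are the
    shared reference table, so zero-distortion builds are exactly clean."""

    bonds: dict = field(default_factory=lambda: dict(BOND_REFERENCE))
    angles: dict = field(default_factory=lambda: dict(ANGLE_REFERENCE))

    def bond(self, key: str) -> float:
        return self.bonds[key][0]

    def bond_esd(self, key: str) -> float:
        return self.bonds[key][1]

    def angle(self, key: str) -> float:
        return self.angles[key][0]


def place_atom(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point at the given internal coordinates relative to
    three reference points (natural extension reference frame): distance
    ``bond`` from p3, angle p2-p3-new of ``angle`` degrees, dihedral
    p1-p2-p3-new of ``torsion`` degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


#: improper dihedral N-C-CA-CB placing CB with L-amino-acid chirality
_CB_IMPROPER = 120.0
_CB_ANGLE = 110.1  # C-CA-CB, degrees


def build_backbone(sequence, phi, psi, omega, params: GeometryParams | None = None,
                   chain_id: str = "A", first_seq_number: int = 1,
                   b_factors=None,
                   bond_overrides: dict[tuple[int, str], float] | None = None,
                   ) -> Chain:
    """Build an N/CA/C/O(/CB) backbone chain from dihedral targets.

    ``sequence`` is a string of one-letter codes or list of three-letter
    codes; ``phi``/``psi`` have one value per residue (phi of the first
    and psi of the last are still used to place O consistently but have
    no torsional meaning); ``omega`` has one value per peptide bond
    (length n-1).  ``bond_overrides`` maps (residue_index, bond_key) to a
    replacement bond length, used to inject covalent-geometry distortions
    of known magnitude.  CB is placed tetrahedrally on non-Gly residues;
    the carbonyl O sits in the peptide plane.
    """
    gp = params or GeometryParams()
    seq3 = [AA1_TO_3[a] if len(a) == 1 else a.upper() for a in sequence]
    n = len(seq3)
    if not (len(phi) == len(psi) == n and len(omega) == n - 1):
        raise ValueError("sequence/dihedral length mismatch")
    overrides = bond_overrides or {}
    b_factors = b_factors if b_factors is not None else [15.0] * n

    def blen(i: int, key: str) -> float:
        return overrides.get((i, key), gp.bond(key))

    positions: list[dict[str, np.ndarray]] = []
    for i in range(n):
        pos: dict[str, np.ndarray] = {}
        if i == 0:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([blen(0, "N-CA"), 0.0, 0.0])
            ang = np.radians(gp.angle("N-CA-C"))
            pos["C"] = pos["CA"] + blen(0, "CA-C") * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = positions[i - 1]
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  blen(i - 1, "C-N+"), gp.angle("CA-C-N+"),
                                  psi[i - 1])
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   blen(i, "N-CA"), gp.angle("-C-N-CA"),
                                   omega[i - 1])
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  blen(i, "CA-C"), gp.angle("N-CA-C"), phi[i])
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                              blen(i, "C-O"), gp.angle("CA-C-O"),
                              psi[i] + 180.0)
        if seq3[i] != "GLY":
            pos["CB"] = place_atom(pos["N"], pos["C"], pos["CA"],
                                   blen(i, "CA-CB"), _CB_ANGLE, _CB_IMPROPER)
        positions.append(pos)

    residues = []
    for i, (aa, pos) in enumerate(zip(seq3, positions)):
        atoms = [Atom(name=name, element=name[0], position=p,
                      b_factor=round(float(b_factors[i]), 2))
                 for name, p in pos.items()]
        residues.append(Residue(chain_id=chain_id,
                                seq_number=first_seq_number + i,
                                insertion_code="", aa_type=aa, atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# scenario generation


@dataclass
class Corruption:
    """One corruption directive applied at a planted cis bond.

    kind: high_b | geometry_distort | clash_inject | terminal_cis |
    tandem_cis; magnitude is esd multiples for geometry_distort and the
    target overlap in Angstrom for clash_inject.
    """

    kind: str
    magnitude: float = 0.0


@dataclass
class ChainSpec:
    sequence: list[str]             # three-letter codes
    cis_bonds: list[int]            # bond indices (0-based, bond i = res i -> i+1)
    corruption: Corruption | None = None
    phi: list[float] | None = None
    psi: list[float] | None = None
    omega: list[float] | None = None


@dataclass
class ScenarioSpec:
    chains: list[ChainSpec]
    seed: int
    resolution: float = 1.5
    b_ordered: tuple[float, float] = (15.0, 3.0)
    b_disordered: tuple[float, float] = (70.0, 10.0)


@dataclass
class SyntheticCase:
    structures: dict[str, Structure]
    truth: pd.DataFrame              # pdb, chain, res1, res2, kind, directive
    annotations: dict[str, dict[tuple[str, int, str], ResidueAnnotation]]
    seed: int


# local conformation given to planted cis bonds: beta-like first residue,
# the second residue phi pulled toward the observed cis-nonPro basin so the
# two flanking strands do not collide across the short CA-CA link
_CIS_PHI2 = -90.0
_BETA_PHI, _BETA_PSI = -120.0, 130.0


def _default_dihedrals(n: int, cis_bonds: list[int], rng: np.random.Generator):
    phi = [_BETA_PHI] * n
    psi = [_BETA_PSI] * n
    omega = [180.0] * (n - 1)
    for b in cis_bonds:
        omega[b] = float(np.round(rng.normal(0.0, 4.0), 2))
        phi[b + 1] = _CIS_PHI2
    return phi, psi, omega


def generate_case(spec: ScenarioSpec) -> SyntheticCase:
    """Realise a scenario: one single-chain structure per chain spec, a
    ground-truth table of planted bonds, and a density-annotation table
    drawn consistently with each residue's order/disorder state.
    Deterministic given the spec (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    structures: dict[str, Structure] = {}
    annotations: dict[str, dict] = {}
    truth_rows = []
    for ci, cs in enumerate(spec.chains):
        entry = f"s{ci:04d}"
        n = len(cs.sequence)
        corruption = cs.corruption
        cis_bonds = sorted(cs.cis_bonds)
        if corruption is not None and corruption.kind == "terminal_cis":
            cis_bonds = [0]
        if corruption is not None and corruption.kind == "tandem_cis":
            mid = n // 2
            cis_bonds = [mid, mid + 1]
        for b in cis_bonds:
            if not 0 <= b < n - 1:
                raise ValueError(f"chain {ci}: cis bond index {b} out of range")
            if cs.sequence[b + 1] == "PRO":
                raise ValueError(f"chain {ci}: planted cis bond precedes Pro")
        phi, psi, omega = _default_dihedrals(n, cis_bonds, rng)
        if cs.phi is not None:
            phi = list(cs.phi)
        if cs.psi is not None:
            psi = list(cs.psi)
        if cs.omega is not None:
            omega = list(cs.omega)

        disordered = np.zeros(n, dtype=bool)
        overrides = {}
        if corruption is not None and cis_bonds:
            b0 = cis_bonds[0]
            if corruption.kind == "high_b":
                lo, hi = max(0, b0 - 2), min(n, b0 + 4)
                disordered[lo:hi] = True
            elif corruption.kind == "geometry_distort":
                overrides[(b0, "N-CA")] = (BOND_REFERENCE["N-CA"][0] +
                                           corruption.magnitude * BOND_REFERENCE["N-CA"][1])
            elif corruption.kind not in ("clash_inject", "terminal_cis", "tandem_cis"):
                raise ValueError(f"unknown corruption kind {corruption.kind!r}")

        mean_o, sd_o = spec.b_ordered
        mean_d, sd_d = spec.b_disordered
        b_factors = np.where(disordered,
                             rng.normal(mean_d, sd_d, size=n),
                             rng.normal(mean_o, sd_o, size=n))
        b_factors = np.clip(b_factors, 2.0, 150.0)
        chain = build_backbone(cs.sequence, phi, psi, omega, chain_id="A",
                               b_factors=b_factors, bond_overrides=overrides)
        st = Structure(entry_id=entry, chains=[chain], resolution=spec.resolution)

        if corruption is not None and corruption.kind == "clash_inject" and cis_bonds:
            target = chain.residues[cis_bonds[0]]
            ca = target.atom("CA")
            cb = target.atom("CB")
            if cb is not None:
                anchor = cb
                direction = cb.position - ca.position
            else:  # Gly: push out along the N/C bisector instead of CB
                anchor = ca
                direction = ca.position - 0.5 * (target.atom("N").position +
                                                 target.atom("C").position)
            direction = direction / np.linalg.norm(direction)
            d = 2.0 * 1.70 - corruption.magnitude
            pos = np.round(anchor.position + d * direction, 3)
            st.ligand_atoms.append(LigandAtom(
                chain_id="X", res_name="LIG", seq_number=1,
                atom=Atom(name="C1", element="C", position=pos, b_factor=20.0)))

        ann: dict[tuple[str, int, str], ResidueAnnotation] = {}
        for i, r in enumerate(chain.residues):
            if disordered[i]:
                rscc = float(np.round(rng.uniform(0.40, 0.69), 3))
                map_sigma = float(np.round(rng.uniform(0.3, 1.1), 2))
            else:
                rscc = float(np.round(rng.uniform(0.85, 0.98), 3))
                map_sigma = float(np.round(rng.uniform(1.5, 4.0), 2))
            ann[r.key] = ResidueAnnotation(chain_id="A", seq_number=r.seq_number,
                                           rscc=rscc, map_sigma=map_sigma)
        structures[entry] = st
        annotations[entry] = ann
        for b in cis_bonds:
            truth_rows.append({
                "pdb": entry, "chain": "A",
                "res1": chain.residues[b].seq_number,
                "res2": chain.residues[b + 1].seq_number,
                "kind": "genuine_cis_nonpro" if corruption is None else "decoy",
                "directive": corruption.kind if corruption else "none",
            })
    truth = pd.DataFrame(truth_rows, columns=["pdb", "chain", "res1", "res2",
                                              "kind", "directive"])
    return SyntheticCase(structures=structures, truth=truth,
                         annotations=annotations, seed=spec.seed)


_SCENARIO_AAS = [aa for aa in UNIPROT_FREQUENCIES if aa != "PRO"]
_SCENARIO_WEIGHTS = np.array([UNIPROT_FREQUENCIES[aa] for aa in _SCENARIO_AAS])
_SCENARIO_WEIGHTS = _SCENARIO_WEIGHTS / _SCENARIO_WEIGHTS.sum()


def standard_scenario(seed: int, n_chains: int = 50, chain_length: int = 24,
                      n_clean: int = 12,
                      decoy_kinds: tuple = (("high_b", 0.0), ("high_b", 0.0),
                                            ("high_b", 0.0),
                                            ("geometry_distort", 5.0),
                                            ("geometry_distort", 5.0),
                                            ("geometry_distort", 5.0),
                                            ("clash_inject", 1.0),
                                            ("clash_inject", 1.0),
                                            ("terminal_cis", 0.0),
                                            ("terminal_cis", 0.0),
                                            ("tandem_cis", 0.0)),
                      ) -> ScenarioSpec:
    """The benchmark scenario: ``n_clean`` chains with one clean planted
    cis-nonPro each, one decoy chain per entry of ``decoy_kinds`` (the
    tandem directive plants two adjacent cis bonds, i.e. two decoy
    records), and the remainder all-trans.  Proline is excluded from the
    sampled sequences so every planted cis bond is cis-nonPro."""
    rng = np.random.default_rng(seed)
    chains: list[ChainSpec] = []
    mid = chain_length // 2
    for i in range(n_chains):
        seq = list(rng.choice(_SCENARIO_AAS, size=chain_length,
                              p=_SCENARIO_WEIGHTS))
        if i < n_clean:
            chains.append(ChainSpec(sequence=seq, cis_bonds=[mid]))
        elif i - n_clean < len(decoy_kinds):
            kind, mag = decoy_kinds[i - n_clean]
            chains.append(ChainSpec(sequence=seq, cis_bonds=[mid],
                                    corruption=Corruption(kind, mag)))
        else:
            chains.append(ChainSpec(sequence=seq, cis_bonds=[]))
    return ScenarioSpec(chains=chains, seed=seed)


# ---------------------------------------------------------------------------
# survey sampling


@dataclass
class SurveySampleParams:
    """Generator settings for a chain/record survey sample.

    ``counts_cazy`` / ``counts_noncazy`` give the per-chain distribution of
    curated-record counts (count -> probability) for CAZy and non-CAZy
    chains; together with ``cazy_fraction`` they fix the expected
    enrichment folds, which :func:`expected_chain_fold` and
    :func:`expected_multi_fold` compute analytically.
    """

    n_chains: int = 6765
    cazy_fraction: float = 0.06
    counts_cazy: dict[int, float] = field(default_factory=lambda: {0: 0.94, 1: 0.06})
    counts_noncazy: dict[int, float] = field(default_factory=lambda: {0: 0.94, 1: 0.06})

    def __post_init__(self) -> None:
        if not 0.0 < self.cazy_fraction < 1.0:
            raise ValueError("cazy_fraction must be in (0, 1)")
        for dist in (self.counts_cazy, self.counts_noncazy):
            if any(p < 0 for p in dist.values()) or \
                    abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("count distribution must be a probability vector")

    @classmethod
    def with_chain_fold(cls, fold: float, n_chains: int = 5000,
                        cazy_fraction: float = 0.06,
                        base_rate: float = 0.06) -> "SurveySampleParams":
        """Parameters whose expected chain-level CAZy enrichment is ``fold``.

        base_rate is the marginal probability that a chain carries a
        record.  Infeasible folds (requiring negative or >1 per-stratum
        rates) raise ValueError.
        """
        f = cazy_fraction
        q_c = fold * base_rate
        q_n = base_rate * (1.0 - fold * f) / (1.0 - f)
        if not (0.0 <= q_c <= 1.0 and 0.0 <= q_n <= 1.0):
            raise ValueError(
                f"fold {fold} infeasible at cazy_fraction {f}, base rate {base_rate}")
        return cls(n_chains=n_chains, cazy_fraction=f,
                   counts_cazy={0: 1.0 - q_c, 1: q_c},
                   counts_noncazy={0: 1.0 - q_n, 1: q_n})

    @classmethod
    def with_multi_fold(cls, fold: float, n_chains: int = 5000,
                        cazy_fraction: float = 0.06,
                        single_rate: float = 0.05) -> "SurveySampleParams":
        """Parameters whose expected multi-occurrence fold is ``fold``:
        chains carry one record at ``single_rate`` and a pair at the rate
        solving fold = (2 p2 / (p1 + 2 p2)) / p2."""
        p1 = single_rate
        p2 = (2.0 / fold - p1) / 2.0
        if not 0.0 < p2 < 1.0 - p1:
            raise ValueError(f"multi fold {fold} infeasible at single rate {p1}")
        dist = {0: 1.0 - p1 - p2, 1: p1, 2: p2}
        return cls(n_chains=n_chains, cazy_fraction=cazy_fraction,
                   counts_cazy=dict(dist), counts_noncazy=dict(dist))


def _dist_moments(dist: dict[int, float]) -> tuple[float, float, float]:
    """(P(count>=1), E[count], E[count | multi-part]) helper moments."""
    p_any = sum(p for c, p in dist.items() if c >= 1)
    mean = sum(c * p for c, p in dist.items())
    multi_mass = sum(c * p for c, p in dist.items() if c > 1)
    return p_any, mean, multi_mass


def expected_chain_fold(params: SurveySampleParams) -> float:
    f = params.cazy_fraction
    pc, _, _ = _dist_moments(params.counts_cazy)
    pn, _, _ = _dist_moments(params.counts_noncazy)
    observed = f * pc / (f * pc + (1 - f) * pn)
    return observed / f


def expected_multi_fold(params: SurveySampleParams) -> float:
    f = params.cazy_fraction
    _, mc, mmc = _dist_moments(params.counts_cazy)
    _, mn, mmn = _dist_moments(params.counts_noncazy)
    p_multi_c = sum(p for c, p in params.counts_cazy.items() if c > 1)
    p_multi_n = sum(p for c, p in params.counts_noncazy.items() if c > 1)
    record_frac = (f * mmc + (1 - f) * mmn) / (f * mc + (1 - f) * mn)
    chain_frac = f * p_multi_c + (1 - f) * p_multi_n
    return record_frac / chain_frac


_CAZY_FAMILY_POOL = [f"GH{i}" for i in (18, 5, 1, 10, 2, 13, 16, 20, 27, 31)] + \
    [f"PL{i}" for i in (1, 3, 4, 8)]


def sample_survey_dataset(params: SurveySampleParams, seed: int,
                          background: BackgroundFrequencies | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic survey sample: a chain-annotation table for every
    reference chain and a curated-record table for the chains that carry
    cis-nonPro records.  First-position amino acids follow the background
    frequencies; second positions exclude Pro (renormalised).  Pure
    function of (params, seed)."""
    bg = background or BackgroundFrequencies.uniprot()
    rng = np.random.default_rng(seed)
    aas = list(bg.frequencies)
    p1 = np.array([bg.frequencies[a] for a in aas])
    p1 = p1 / p1.sum()
    aas2 = [a for a in aas if a != "PRO"]
    p2 = np.array([bg.frequencies[a] for a in aas2])
    p2 = p2 / p2.sum()

    is_cazy = rng.random(params.n_chains) < params.cazy_fraction
    chain_rows = []
    record_rows = []
    for i in range(params.n_chains):
        pdb = f"c{i:05d}"
        cazy = bool(is_cazy[i])
        family = str(rng.choice(_CAZY_FAMILY_POOL)) if cazy else ""
        resolution = float(np.round(rng.uniform(1.0, 1.95), 2))
        chain_rows.append({"pdb": pdb, "chain": "A",
                           "cazy_families": family, "resolution": resolution})
        dist = params.counts_cazy if cazy else params.counts_noncazy
        counts = sorted(dist)
        n_rec = int(rng.choice(counts, p=[dist[c] for c in counts]))
        for j in range(n_rec):
            aa1 = str(rng.choice(aas, p=p1))
            aa2 = str(rng.choice(aas2, p=p2))
            record_rows.append({
                "pdb": pdb, "chain": "A",
                "res1": 10 * (j + 1), "aa1": aa1,
                "res2": 10 * (j + 1) + 1, "aa2": aa2,
                "resolution": resolution,
                "n_cis_nonpro_in_chain": n_rec,
                "in_cazy": cazy, "cazy_family": family,
                "fold_label": "", "molecule_name": "",
                "omega": float(np.round(np.clip(rng.normal(0.0, 6.0), -29, 29), 2)),
                "verdict": "genuine", "flags": "", "notes": "",
            })
    return pd.DataFrame(record_rows), pd.DataFrame(chain_rows)
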