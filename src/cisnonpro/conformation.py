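"""Five-dimensional (phi1, psi1, omega, phi2, psi2) conformational analysis.

Each curated cis-nonPro bond spans two residues, so its local backbone
conformation lives in an expanded Ramachandran space: phi/psi of the first
residue, the bond's omega, and phi/psi of the second.  Clustering in this
space separates the recurring functional motifs (e.g. the TIM-barrel
beta-strand-end cluster, the distinct Gly-cis-Gly clusters).  Because all
five coordinates are angles, distances are circular: each per-angle
difference is wrapped into [0, 180] before the root-mean-square is taken.

The clustering is a deterministic density-based procedure (DBSCAN over the
precomputed circular distance matrix, inputs canonically ordered by record
key) so that cluster labels are reproducible, unlike the interactive
cluster-picking the motifs were originally described with.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from .geometry import backbone_phi_psi, wrap_degrees
from .model import CisNonProRecord, Structure

ANGLE_NAMES = ("phi1", "psi1", "omega", "phi2", "psi2")


@dataclass
class DihedralQuintet:
    record_key: tuple[str, str, int, str]  # (pdb, chain, res1, icode1)
    aa1: str
    aa2: str
    phi1: float | None
    psi1: float | None
    omega: float | None
    phi2: float | None
    psi2: float | None

    def angles(self) -> tuple[float | None, ...]:
        return (self.phi1, self.psi1, self.omega, self.phi2, self.psi2)

    @property
    def complete(self) -> bool:
        return all(a is not None for a in self.angles())


def extract_quintets(records: list[CisNonProRecord],
                     structures: dict[str, Structure]) -> list[DihedralQuintet]:
    """Pull the five local dihedrals for each record from its structure.

    Records sitting next to a chain end or break keep their partial
    quintet (absent angles stay None) but are excluded from clustering.
    """
    quintets = []
    dihedral_cache: dict[tuple[str, str], object] = {}
    for rec in records:
        st = structures[rec.pdb]
        chain = st.chain(rec.chain)
        if chain is None:
            continue
        cache_key = (rec.pdb, rec.chain)
        if cache_key not in dihedral_cache:
            dihedral_cache[cache_key] = backbone_phi_psi(chain)
        dih = dihedral_cache[cache_key]
        k1 = (rec.chain, rec.res1, rec.icode1)
        k2 = (rec.chain, rec.res2, rec.icode2)
        quintets.append(DihedralQuintet(
            record_key=(rec.pdb, rec.chain, rec.res1, rec.icode1),
            aa1=rec.aa1, aa2=rec.aa2,
            phi1=dih.phi.get(k1), psi1=dih.psi.get(k1),
            omega=rec.omega,
            phi2=dih.phi.get(k2), psi2=dih.psi.get(k2),
        ))
    return quintets


def circular_distance(q1: DihedralQuintet, q2: DihedralQuintet) -> float:
    """Root-mean-square of the five wrapped per-angle differences, degrees."""
    if not (q1.complete and q2.complete):
        raise ValueError("circular distance requires complete quintets")
    d = np.abs(wrap_degrees(np.array(q1.angles()) - np.array(q2.angles())))
    return float(np.sqrt(np.mean(d ** 2)))


@dataclass
class ClusterAssignment:
    record_key: tuple[str, str, int, str]
    label: int  # -1 = noise
    medoid_key: tuple[str, str, int, str] | None


def cluster_quintets(quintets: list[DihedralQuintet], radius: float = 30.0,
                     min_members: int = 3) -> list[ClusterAssignment]:
    """Density-based clustering of complete quintets under the circular
    metric.

    Core points have at least ``min_members`` neighbours (the point
    itself included) within ``radius``; clusters are connected components
    of core points plus their border points; everything else is noise
    (label -1).  Inputs are sorted by record key and cluster labels are
    renumbered by their smallest member key, so the assignment is a pure
    function of the quintet set, independent of input order.
    """
    complete = sorted((q for q in quintets if q.complete),
                      key=lambda q: q.record_key)
    if not complete:
        return []
    mat = np.array([[wrap_degrees(a) for a in q.angles()] for q in complete])
    diff = np.abs(wrap_degrees(mat[:, None, :] - mat[None, :, :]))
    dist = np.sqrt(np.mean(diff ** 2, axis=2))
    labels = DBSCAN(eps=radius, min_samples=min_members,
                    metric="precomputed").fit(dist).labels_
    # canonical relabelling by smallest member key
    order: dict[int, int] = {}
    for lab in labels:
        if lab != -1 and lab not in order:
            order[lab] = len(order)
    medoids: dict[int, tuple] = {}
    for lab in set(labels):
        if lab == -1:
            continue
        idx = np.flatnonzero(labels == lab)
        within = dist[np.ix_(idx, idx)].sum(axis=1)
        medoids[lab] = complete[idx[int(np.argmin(within))]].record_key
    return [ClusterAssignment(record_key=q.record_key,
                              label=order.get(lab, -1) if lab != -1 else -1,
                              medoid_key=medoids.get(lab))
            for q, lab in zip(complete, labels)]


# ---------------------------------------------------------------------------
# Ramachandran regions

#: (phi_min, phi_max, psi intervals) boxes covering the canonical basins
BETA_BOX = {"phi": (-180.0, -45.0), "psi": ((60.0, 180.0), (-180.0, -150.0))}
ALPHA_BOX = {"phi": (-100.0, -30.0), "psi": ((-112.0, -22.0),)}


def region_label(phi: float, psi: float, beta_box: dict = BETA_BOX,
                 alpha_box: dict = ALPHA_BOX) -> str:
    """Coarse Ramachandran region of a (phi, psi) pair: beta, alpha or
    other, using configurable rectangular boxes over the canonical
    basins."""
    phi, psi = wrap_degrees(phi), wrap_degrees(psi)

    def in_box(box: dict) -> bool:
        lo, hi = box["phi"]
        return lo <= phi <= hi and any(a <= psi <= b for a, b in box["psi"])

    if in_box(beta_box):
        return "beta"
    if in_box(alpha_box):
        return "alpha"
    return "other"


# ---------------------------------------------------------------------------
# omega distribution


def omega_distribution_stats(omegas) -> dict:
    """Circular mean/SD, skew sign and range of a sample of omega values.

    The skew sign comes from the third central moment of the values
    wrapped around the circular mean; a negative sign means the long tail
    of the cis distribution extends to negative omega.
    """
    omegas = np.asarray([o for o in omegas if o is not None], dtype=float)
    if omegas.size < 2:
        raise ValueError("need at least 2 omega values")
    mean = float(stats.circmean(omegas, high=180.0, low=-180.0))
    sd = float(stats.circstd(omegas, high=180.0, low=-180.0))
    centered = wrap_degrees(omegas - mean)
    m3 = float(np.mean(np.asarray(centered) ** 3))
    return {
        "circular_mean": mean,
        "circular_sd": sd,
        "skew_sign": int(np.sign(round(m3, 9))),
        "min": float(omegas.min()),
        "max": float(omegas.max()),
        "n": int(omegas.size),
    }


# ---------------------------------------------------------------------------
# projections


def projection_export(quintets: list[DihedralQuintet],
                      axes: tuple[str, str] = ("psi1", "phi2"),
                      path: str | Path | None = None,
                      assignments: list[ClusterAssignment] | None = None,
                      ) -> pd.DataFrame:
    """Two-dimensional projection table of the quintet set (default the
    psi1 x phi2 plane, the most diagnostic projection), carrying the
    sequence pair and optional cluster labels, written as CSV when a path
    is given."""
    for ax in axes:
        if ax not in ANGLE_NAMES:
            raise ValueError(f"unknown axis {ax!r}; choose from {ANGLE_NAMES}")
    labels = {a.record_key: a.label for a in (assignments or [])}
    rows = []
    for q in quintets:
        rows.append({
            "record": "{}/{}/{}{}".format(*q.record_key),
            "aa1": q.aa1, "aa2": q.aa2,
            axes[0]: getattr(q, axes[0]),
            axes[1]: getattr(q, axes[1]),
            "cluster": labels.get(q.record_key, -1),
        })
    df = pd.DataFrame(rows, columns=["record", "aa1", "aa2", *axes, "cluster"])
    if path is not None:
        df.to_csv(path, index=False, float_format="%.4f")
    return df
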