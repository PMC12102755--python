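"""SYNTHETIC reconstruction of a curated cis-nonPro survey list.

The published curated list (one row per reliability-filtered cis-nonPro
peptide, with chain, CAZy and omega annotations) is distributed as
supplementary material that is not shipped here.  This module builds a
synthetic stand-in with the same schema whose *marginal tallies* equal the
published headline numbers:

* 439 peptides in 378 distinct chains;
* 99 CAZy chains carrying 144 peptides (295 in 279 non-CAZy chains);
* 43 chains with more than one peptide, 33 of them CAZy;
* 43 distinct CAZy families, with the large families (GH18 17 chains,
  GH5 13, GH1 11, GH10 8, GH2 5) at their published sizes;
* 19 Gly-cis-Gly, 59 Gly-cis-X and 15 X-cis-Gly (X != Gly);
* 49 Trp-cis-X and 13 X-cis-Trp, with no Trp-cis-Trp;
* omega values tightly spread around 0 with a negative-side tail.

Everything below the marginals (which chain carries which sequence pair,
residue numbering, exact omega values) is invented, deterministically from
the seed.  The published counts are mutually inconsistent by one peptide
(99 CAZy chains of which 33 multi-record holding 77 peptides implies 143,
not 144, CAZy peptides); the reconstruction keeps 99/33/144, so its multi
CAZy chains hold 78 peptides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import RECORD_COLUMNS
from .refdata import AA3, UNIPROT_FREQUENCIES

# published headline tallies the reconstruction reproduces
N_PEPTIDES = 439
N_CAZY_PEPTIDES = 144
N_CAZY_CHAINS = 99
N_NONCAZY_CHAINS = 279
CAZY_MULTI = {3: 12, 2: 21}      # 33 multi chains, 78 peptides
NONCAZY_MULTI = {3: 6, 2: 4}     # 10 multi chains, 26 peptides
GLY_GLY, GLY_X, X_GLY = 19, 59, 15
TRP_X, X_TRP = 49, 13

_BIG_FAMILIES = [("GH18", 17), ("GH5", 13), ("GH1", 11), ("GH10", 8), ("GH2", 5)]
_PL_FAMILIES = ["PL1", "PL3", "PL4", "PL8"]
_PAIRED_FAMILIES = ["GH3", "GH6", "GH7", "GH8", "GH9", "GH11", "GH12"]
_SINGLE_FAMILIES = [f"GH{i}" for i in range(13, 36) if i != 18] + \
    ["GT2", "GT4", "GT35", "CE1", "CE4"]


def _family_list() -> list[str]:
    """One CAZy family label per CAZy chain; 43 distinct families, 99 chains."""
    fams: list[str] = []
    for fam, count in _BIG_FAMILIES:
        fams.extend([fam] * count)
    fams.extend(_PL_FAMILIES)
    for fam in _PAIRED_FAMILIES:
        fams.extend([fam] * 2)
    fams.extend(_SINGLE_FAMILIES[:27])
    assert len(fams) == N_CAZY_CHAINS and len(set(fams)) == 43
    return fams


def _sample_aa(rng: np.random.Generator, exclude: tuple[str, ...]) -> str:
    aas = [a for a in AA3 if a not in exclude]
    p = np.array([UNIPROT_FREQUENCIES[a] for a in aas])
    return str(rng.choice(aas, p=p / p.sum()))


def _sequence_pairs(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Ordered (first, second) pairs with the published motif marginals.

    Categories are kept disjoint so each marginal is exact: the 59
    Gly-cis-X and 49 Trp-cis-X draw X outside {Gly, Trp, Pro}; the 15
    X-cis-Gly and 13 X-cis-Trp draw X outside {Gly, Trp}; the remainder
    avoids Gly and Trp in either position and Pro in the second.
    """
    pairs: list[tuple[str, str]] = []
    pairs += [("GLY", "GLY")] * GLY_GLY
    pairs += [("GLY", _sample_aa(rng, ("GLY", "TRP", "PRO"))) for _ in range(GLY_X)]
    pairs += [(_sample_aa(rng, ("GLY", "TRP")), "GLY") for _ in range(X_GLY)]
    pairs += [("TRP", _sample_aa(rng, ("GLY", "TRP", "PRO"))) for _ in range(TRP_X)]
    pairs += [(_sample_aa(rng, ("GLY", "TRP")), "TRP") for _ in range(X_TRP)]
    n_rest = N_PEPTIDES - len(pairs)
    pairs += [(_sample_aa(rng, ("GLY", "TRP")),
               _sample_aa(rng, ("GLY", "TRP", "PRO"))) for _ in range(n_rest)]
    rng.shuffle(pairs)  # type: ignore[arg-type]
    return [tuple(p) for p in pairs]


def _omega_values(rng: np.random.Generator, n: int) -> np.ndarray:
    """Cis omega sample: tight spread around 0 with a negative tail."""
    core = np.clip(rng.normal(0.0, 5.0, size=n), -14.0, 14.0)
    tail_idx = rng.choice(n, size=max(3, n // 25), replace=False)
    core[tail_idx] = rng.uniform(-28.0, -15.0, size=tail_idx.size)
    return np.round(core, 2)


def synthetic_curated_list(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the synthetic curated-list table and its chain-annotation
    table.  Returns (records, chain_annotations) DataFrames in the
    canonical schemas."""
    rng = np.random.default_rng(seed)
    families = _family_list()
    rng.shuffle(families)

    # per-chain record counts: CAZy multi first, then singles, then non-CAZy
    chain_plan: list[tuple[bool, int]] = []
    for count, n in CAZY_MULTI.items():
        chain_plan += [(True, count)] * n
    chain_plan += [(True, 1)] * (N_CAZY_PEPTIDES - sum(c * n for c, n in CAZY_MULTI.items()))
    for count, n in NONCAZY_MULTI.items():
        chain_plan += [(False, count)] * n
    n_noncazy_multi_records = sum(c * n for c, n in NONCAZY_MULTI.items())
    chain_plan += [(False, 1)] * (295 - n_noncazy_multi_records)

    pairs = _sequence_pairs(rng)
    omegas = _omega_values(rng, N_PEPTIDES)

    fam_iter = iter(families)
    record_rows = []
    chain_rows = []
    pair_idx = 0
    for i, (cazy, count) in enumerate(chain_plan):
        pdb = f"x{i:03d}"
        family = next(fam_iter) if cazy else ""
        resolution = float(np.round(rng.uniform(0.9, 1.95), 2))
        chain_rows.append({"pdb": pdb, "chain": "A", "cazy_families": family,
                           "molecule_name": "synthetic survey chain",
                           "fold_label": "", "resolution": resolution})
        for j in range(count):
            aa1, aa2 = pairs[pair_idx]
            record_rows.append({
                "pdb": pdb, "chain": "A",
                "res1": 25 * (j + 1), "aa1": aa1,
                "res2": 25 * (j + 1) + 1, "aa2": aa2,
                "resolution": resolution,
                "n_cis_nonpro_in_chain": count,
                "in_cazy": cazy, "cazy_family": family,
                "fold_label": "", "molecule_name": "synthetic survey chain",
                "omega": float(omegas[pair_idx]),
                "verdict": "genuine", "flags": "", "notes": "synthetic",
            })
            pair_idx += 1
    records = pd.DataFrame(record_rows, columns=RECORD_COLUMNS)
    chains = pd.DataFrame(chain_rows)
    return records, chains
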