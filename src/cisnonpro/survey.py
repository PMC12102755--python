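"""Enrichment and frequency statistics over a curated cis-nonPro list.

All operations work on the record table (one row per curated cis peptide
bond) plus chain-level metadata, so every survey number is recomputable
from the table alone: CAZy over-representation folds at the chain and at
the multi-occurrence level, position-specific amino-acid frequency tables
with sigma-tier flags against a background frequency set, ordered-pair
motif tallies with independence expectations, and per-chain count
histograms.

Significance tiers compare an observed count against its expectation
n*p under the background frequencies.  The default sigma is the Poisson
sqrt(n*p); a binomial sqrt(n*p*(1-p)) alternative is available.  The
Poisson form reproduces the published flag pattern of the occurrence
table in full, which the binomial form does not (it over-flags two cells
sitting just inside the 3-sigma boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .refdata import (AA3, AA3_TO_1, PUBLISHED_POSITION_COUNTS,
                      PUBLISHED_POSITION_TOTALS, UNIPROT_FREQUENCIES)


@dataclass
class BackgroundFrequencies:
    """Per-amino-acid background fractions (sum 1 within 1e-3)."""

    frequencies: dict[str, float]
    source: str = "UniProtKB"

    def __post_init__(self) -> None:
        if set(self.frequencies) != set(AA3):
            raise ValueError("background must cover exactly the 20 standard amino acids")
        if any(not 0.0 < p < 1.0 for p in self.frequencies.values()):
            raise ValueError("background fractions must lie in (0, 1)")
        # tolerance accommodates published rounded percentage columns
        # (the default UniProt column itself sums to 99.85%)
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 2e-3:
            raise ValueError(f"background fractions sum to {total}, not 1")

    @classmethod
    def uniprot(cls) -> "BackgroundFrequencies":
        return cls(dict(UNIPROT_FREQUENCIES), source="UniProtKB")

    @classmethod
    def from_file(cls, path: str | Path) -> "BackgroundFrequencies":
        """Two-column CSV (aa, fraction-or-percent); percent detected by sum."""
        df = pd.read_csv(path, header=None, names=["aa", "value"], comment="#")
        freqs = {}
        for _, row in df.iterrows():
            aa = str(row["aa"]).strip().upper()
            aa3 = aa if aa in AA3 else {v: k for k, v in AA3_TO_1.items()}.get(aa)
            if aa3 not in AA3:
                raise ValueError(f"unknown amino acid {row['aa']!r}")
            freqs[aa3] = float(row["value"])
        total = sum(freqs.values())
        if total > 2.0:  # given as percentages
            freqs = {k: v / 100.0 for k, v in freqs.items()}
        return cls(freqs, source=str(path))

    def p(self, aa: str) -> float:
        return self.frequencies[aa]


@dataclass
class EnrichmentResult:
    observed_count: int
    observed_total: int
    background_fraction: float
    background_count: int | None = None
    background_total: int | None = None

    @property
    def observed_fraction(self) -> float:
        return self.observed_count / self.observed_total

    @property
    def fold(self) -> float:
        if self.observed_count == 0:
            return 0.0
        return self.observed_fraction / self.background_fraction


def _chain_keys(records: pd.DataFrame) -> pd.Series:
    return records["pdb"].astype(str) + "/" + records["chain"].astype(str)


def cazy_enrichment(records: pd.DataFrame,
                    reference_cazy_fraction: float) -> EnrichmentResult:
    """Fold over-representation of CAZy membership among the distinct
    chains carrying at least one curated cis-nonPro, versus the CAZy
    fraction of the reference chain set."""
    if records.empty:
        raise ValueError("no record chains: enrichment undefined")
    per_chain = records.assign(_ck=_chain_keys(records)).groupby("_ck")["in_cazy"].any()
    return EnrichmentResult(
        observed_count=int(per_chain.sum()),
        observed_total=int(per_chain.size),
        background_fraction=reference_cazy_fraction,
    )


def multi_cis_enrichment(records: pd.DataFrame, reference_chain_total: int,
                         cazy_only: bool = False) -> EnrichmentResult:
    """Concentration of curated peptides in chains carrying more than one.

    numerator: fraction of all curated peptides lying in multi-record
    chains (optionally restricted to CAZy multi-record chains);
    denominator: those chains as a fraction of the reference chain set.
    """
    if records.empty:
        raise ValueError("no records: enrichment undefined")
    df = records.assign(_ck=_chain_keys(records))
    counts = df.groupby("_ck").size()
    multi = counts[counts > 1]
    if cazy_only:
        cazy_chains = df.groupby("_ck")["in_cazy"].any()
        multi = multi[cazy_chains.reindex(multi.index).fillna(False)]
    n_multi_records = int(multi.sum())
    return EnrichmentResult(
        observed_count=n_multi_records,
        observed_total=int(len(df)),
        background_fraction=len(multi) / reference_chain_total if len(multi) else math.nan,
        background_count=int(len(multi)),
        background_total=reference_chain_total,
    )


# ---------------------------------------------------------------------------
# sigma tiers


def frequency_z(count: int, n: int, p: float, sigma: str = "poisson") -> float:
    """Signed departure of a count from its expectation n*p, in sigma units."""
    expected = n * p
    if sigma == "poisson":
        sd = math.sqrt(expected)
    elif sigma == "binomial":
        sd = math.sqrt(expected * (1.0 - p))
    else:
        raise ValueError(f"unknown sigma mode {sigma!r}")
    return (count - expected) / sd


def tier_for(z: float, depleted: float = 3.0, over: float = 3.0,
             extreme: float = 12.0) -> str:
    """Map a z value to its flag tier.

    "depleted_3sigma" for z <= -3, "over_3_12sigma" for 3 <= z < 12,
    "over_12sigma" for z >= 12, otherwise "none".  The published marks
    correspond to italic, bold and bold-italic respectively; the gap
    between 6 and 12 sigma is folded into the bold tier, matching how
    such cells are printed.
    """
    if z <= -depleted:
        return "depleted_3sigma"
    if z >= extreme:
        return "over_12sigma"
    if z >= over:
        return "over_3_12sigma"
    return "none"


_TIER_TO_MARK = {"depleted_3sigma": "depleted", "over_3_12sigma": "over",
                 "over_12sigma": "over12", "none": ""}


def aa_frequency_table(records: pd.DataFrame,
                       background: BackgroundFrequencies | None = None,
                       sigma: str = "poisson") -> pd.DataFrame:
    """Occurrence counts of each amino acid in the first and second bond
    position, stratified by CAZy membership, with expectations and tiers.

    Returns one row per (aa, position, stratum): 20 x 2 x 2 = 80 cells.
    Rows with UNK residues are excluded from the counts (and tallied in
    the DataFrame attribute ``n_unk_excluded``).
    """
    bg = background or BackgroundFrequencies.uniprot()
    known = records[(records["aa1"].isin(AA3)) & (records["aa2"].isin(AA3))]
    n_unk = len(records) - len(known)
    cells = []
    for stratum, sub in (("cazy", known[known["in_cazy"]]),
                         ("non_cazy", known[~known["in_cazy"].astype(bool)])):
        for position, col in (("first", "aa1"), ("second", "aa2")):
            n = len(sub)
            counts = sub[col].value_counts()
            for aa in AA3:
                count = int(counts.get(aa, 0))
                p = bg.p(aa)
                z = frequency_z(count, n, p, sigma) if n else math.nan
                # second-position Pro is zero by definition (cis-nonPro),
                # a structural exclusion rather than a depletion
                structural_zero = aa == "PRO" and position == "second"
                cells.append({
                    "aa": aa, "position": position, "stratum": stratum,
                    "count": count, "n": n, "background_p": p,
                    "expected": n * p, "z": z,
                    "tier": "none" if structural_zero or not n else tier_for(z),
                })
    table = pd.DataFrame(cells)
    table.attrs["n_unk_excluded"] = n_unk
    return table


def published_flag_mismatches(sigma: str = "poisson") -> list[dict]:
    """Apply the tier rule to the published occurrence counts and compare
    with the printed italic/bold/bold-italic marks; returns the list of
    mismatching cells (empty when the rule reproduces the table).

    The printed column totals are the sample sizes; second-position Pro
    (a structural zero, forbidden by the cis-nonPro definition) is exempt
    from flagging.
    """
    mismatches = []
    for aa, cols in PUBLISHED_POSITION_COUNTS.items():
        p = UNIPROT_FREQUENCIES[aa]
        for idx, (stratum, position) in enumerate(
                (("cazy", "first"), ("cazy", "second"),
                 ("non_cazy", "first"), ("non_cazy", "second"))):
            count, printed = cols[idx]
            n = PUBLISHED_POSITION_TOTALS[stratum]
            z = frequency_z(count, n, p, sigma)
            if aa == "PRO" and position == "second":
                mark = ""
            else:
                mark = _TIER_TO_MARK[tier_for(z)]
            if mark != printed:
                mismatches.append({"aa": aa, "stratum": stratum,
                                   "position": position, "count": count,
                                   "z": z, "computed": mark, "printed": printed})
    return mismatches


# ---------------------------------------------------------------------------
# motif tallies


def expected_pair_count(n_records: int, aa1: str, aa2: str,
                        background: BackgroundFrequencies) -> float:
    """Independence expectation for the ordered pair (aa1, aa2) with the
    second position renormalised to exclude Pro (forbidden by the
    cis-nonPro definition): N * p(aa1) * p(aa2) / (1 - p(Pro))."""
    if aa2 == "PRO":
        return 0.0
    return n_records * background.p(aa1) * background.p(aa2) / (1.0 - background.p("PRO"))


def motif_tally(records: pd.DataFrame,
                background: BackgroundFrequencies | None = None) -> pd.DataFrame:
    """Counts of every observed ordered (first, second) pair with the
    independence expectation and the reversed-pair ("asymmetry partner")
    count."""
    bg = background or BackgroundFrequencies.uniprot()
    counts = records.groupby(["aa1", "aa2"]).size()
    n = int(len(records))
    rows = []
    for (a1, a2), count in counts.items():
        rows.append({
            "aa1": a1, "aa2": a2, "count": int(count),
            "expected": expected_pair_count(n, a1, a2, bg)
            if a1 in AA3 and a2 in AA3 else math.nan,
            "partner_count": int(counts.get((a2, a1), 0)),
        })
    return pd.DataFrame(rows, columns=["aa1", "aa2", "count", "expected",
                                       "partner_count"])


def motif_marginal(records: pd.DataFrame, aa: str, position: str,
                   exclude_self: bool = True) -> int:
    """Count of records with ``aa`` in the given bond position.

    With ``exclude_self`` (the default) the homo pair is excluded, i.e.
    "Gly-cis-X" counts Gly first with a non-Gly partner -- the reading
    under which the published 59 Gly-cis-X / 15 X-cis-Gly / 19
    Gly-cis-Gly tallies are consistent."""
    col, other = ("aa1", "aa2") if position == "first" else ("aa2", "aa1")
    sub = records[records[col] == aa]
    if exclude_self:
        sub = sub[sub[other] != aa]
    return int(len(sub))


def pair_count(records: pd.DataFrame, aa1: str, aa2: str) -> int:
    return int(((records["aa1"] == aa1) & (records["aa2"] == aa2)).sum())


def chain_record_counts(records: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-chain curated-record counts and the histogram of chains by
    count, binned 1 / 2 / 3 / 4+."""
    counts = records.assign(_ck=_chain_keys(records)).groupby("_ck").size()
    hist = {"1": int((counts == 1).sum()), "2": int((counts == 2).sum()),
            "3": int((counts == 3).sum()), "4+": int((counts >= 4).sum())}
    return counts, hist
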