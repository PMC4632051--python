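"""Expression-linked amino-acid composition statistics.

Per-gene amino-acid frequencies, the proportion of high size/complexity
residues (Pr_HighSC), Spearman correlations between each amino acid's
frequency and Fop across genes, and the four-bin Fop stratification used
to display composition shifts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .codon_model import STANDARD_CODE, GeneticCode, SCScoreTable
from .codon_usage import spearman

__all__ = [
    "aa_frequencies",
    "pr_high_sc",
    "fop_aa_correlations",
    "bin_fop",
    "FOP_BINS",
    "binned_aa_frequencies",
]

FOP_BINS = ("<0.3", "[0.3,0.4)", "[0.4,0.5)", ">=0.5")


def aa_frequencies(
    codon_counts: Mapping[str, int], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Amino-acid frequency vector of one gene (counts translated through
    the genetic code, normalized by total residues; stops excluded).
    Frequencies sum to 1; absent amino acids get 0."""
    totals = {aa: 0 for aa in code.amino_acids}
    n = 0
    for c, k in codon_counts.items():
        aa = code.codon_to_aa.get(c, "*")
        if aa == "*":
            continue
        totals[aa] += k
        n += k
    if n == 0:
        raise ValueError("empty gene: no sense codons")
    return {aa: v / n for aa, v in totals.items()}


def pr_high_sc(freqs: Mapping[str, float], table: SCScoreTable) -> float:
    """Proportion of residues with S/C score above the table's cutoff."""
    high = table.high_sc_set()
    return float(sum(f for aa, f in freqs.items() if aa in high))


def fop_aa_correlations(
    freq_table: pd.DataFrame, fop_values: pd.Series
) -> pd.DataFrame:
    """Spearman R (and two-sided P) between each amino acid's per-gene
    frequency and Fop, over genes with a defined Fop; sorted ascending by
    R. Amino acids with constant frequency are reported with NaN."""
    fop_values = fop_values.dropna()
    common = freq_table.index.intersection(fop_values.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with defined Fop")
    f = freq_table.loc[common]
    y = fop_values.loc[common]
    rows = []
    for aa in f.columns:
        x = f[aa]
        if x.nunique() <= 1:
            r, p = np.nan, np.nan
        else:
            r, p = spearman(x.to_numpy(), y.to_numpy())
        rows.append({"aa": aa, "R": r, "p": p, "n": len(common)})
    tab = pd.DataFrame(rows).set_index("aa")
    tab["sign"] = np.where(tab["R"] > 0, "+", np.where(tab["R"] < 0, "-", "0"))
    return tab.sort_values("R", kind="mergesort")


def bin_fop(fop: float) -> str:
    """Four-category Fop bin: <0.3, [0.3,0.4), [0.4,0.5), >=0.5
    (lower-inclusive except the open first bin)."""
    if not 0.0 <= fop <= 1.0:
        raise ValueError(f"Fop out of range: {fop}")
    if fop < 0.3:
        return FOP_BINS[0]
    if fop < 0.4:
        return FOP_BINS[1]
    if fop < 0.5:
        return FOP_BINS[2]
    return FOP_BINS[3]


def binned_aa_frequencies(
    freq_table: pd.DataFrame, fop_values: pd.Series
) -> pd.DataFrame:
    """Per (amino acid, Fop bin): mean frequency, SE and gene count —
    the data behind a binned-composition display."""
    fop_values = fop_values.dropna()
    common = freq_table.index.intersection(fop_values.index)
    bins = fop_values.loc[common].map(bin_fop)
    rows = []
    for aa in freq_table.columns:
        x = freq_table.loc[common, aa]
        for b in FOP_BINS:
            sel = x[bins == b]
            if len(sel) == 0:
                continue
            se = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else np.nan
            rows.append(
                {"aa": aa, "bin": b, "mean_freq": sel.mean(), "se": se, "n": len(sel)}
            )
    return pd.DataFrame(rows)
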