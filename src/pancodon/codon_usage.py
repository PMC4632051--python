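"""Codon-level statistics: RSCU, class-contrast deltaRSCU with significance
tiers, optimal-codon selection, Fop, ENC and GC3/AT3.

The analysis contrasts relative synonymous codon usage (RSCU) between the
most highly and most lowly expressed gene classes. Per gene and synonymous
family, RSCU(c) = count(c) * family_size / family_total, so uniform usage
gives 1 for every codon. deltaRSCU is the difference of class means of the
per-gene RSCU values (genes lacking an amino acid contribute nothing to
that family's means), tested by a two-sided Welch t-test. Optimal codons
are those with a significantly positive deltaRSCU; per amino acid the
primary optimal codon is, among optimal codons of the best significance
tier present, the one with the largest deltaRSCU (ties: smaller P, then
alphabetical codon).

Significance tiers: "strong" P < 0.001, "significant" P < 0.05, "putative"
0.05 <= P < 0.1, otherwise "ns". User-supplied candidate codons (those a
study flags despite P at or slightly above 0.1) can be injected with an
explicit override list; they are never promoted automatically.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import STANDARD_CODE, GeneticCode
from .cds_io import CdsRecord

__all__ = [
    "rscu",
    "rscu_matrix",
    "delta_rscu",
    "select_optimal_codons",
    "fop",
    "enc",
    "gc3",
    "spearman",
    "mean_abs_delta",
    "compare_distributions",
    "tier_from_p",
    "load_table1_fixture",
    "TIER_STRONG",
    "TIER_SIGNIFICANT",
    "TIER_PUTATIVE",
    "TIER_CANDIDATE",
    "TIER_NS",
]

TIER_STRONG = "strong"
TIER_SIGNIFICANT = "significant"
TIER_PUTATIVE = "putative"
TIER_CANDIDATE = "candidate"  # user-flagged, P at/above 0.1
TIER_NS = "ns"

# rank order used when restricting primary selection to the best tier present
_TIER_RANK = {
    TIER_STRONG: 0,
    TIER_SIGNIFICANT: 1,
    TIER_PUTATIVE: 2,
    TIER_CANDIDATE: 3,
    TIER_NS: 4,
}


def tier_from_p(p: float) -> str:
    if not np.isfinite(p):
        return TIER_NS
    if p < 0.001:
        return TIER_STRONG
    if p < 0.05:
        return TIER_SIGNIFICANT
    if p < 0.1:
        return TIER_PUTATIVE
    return TIER_NS


def _degenerate_codons(code: GeneticCode) -> list[str]:
    return [c for aa in code.degenerate_amino_acids() for c in code.families[aa]]


def rscu(
    codon_counts: Mapping[str, int], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Per-gene RSCU vector.

    Defined only for codons of degenerate amino acids whose family occurs
    in the gene; within such a family of size n with total count m > 0,
    ``rscu(c) = count(c) * n / m`` (family values sum to n).
    """
    out: dict[str, float] = {}
    for aa in code.degenerate_amino_acids():
        fam = code.families[aa]
        m = sum(codon_counts.get(c, 0) for c in fam)
        if m == 0:
            continue
        n = len(fam)
        for c in fam:
            out[c] = codon_counts.get(c, 0) * n / m
    return out


def rscu_matrix(
    records: Iterable[CdsRecord], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Genes x 59-codon matrix of per-gene RSCU (NaN where the gene lacks
    the codon's amino acid)."""
    codons = _degenerate_codons(code)
    rows = {r.gene_id: rscu(r.codon_counts, code) for r in records}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=codons)


def _codon_aa_map(code: GeneticCode) -> pd.Series:
    return pd.Series(
        {c: aa for aa in code.degenerate_amino_acids() for c in code.families[aa]},
        name="aa",
    )


def delta_rscu(
    high: pd.DataFrame,
    low: pd.DataFrame,
    min_genes: int = 10,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Class-contrast table over the 59 degenerate-family codons.

    ``high`` and ``low`` are per-gene RSCU matrices (see
    :func:`rscu_matrix`). Per codon: class means and standard errors over
    the genes in which the codon's amino acid occurs, delta = mean_high -
    mean_low, two-sided Welch t-test, significance tier, and a
    Benjamini-Hochberg q-value column reported alongside the raw P (tier
    assignment always uses raw P). Codons supported by fewer than
    ``min_genes`` genes in either class are flagged ``low_support``.
    """
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both expression classes must contain genes")
    codons = _degenerate_codons(code)
    aa_map = _codon_aa_map(code)
    rows = []
    for c in codons:
        a = high[c].dropna().to_numpy() if c in high else np.array([])
        b = low[c].dropna().to_numpy() if c in low else np.array([])
        row = {
            "codon": c,
            "aa": aa_map[c],
            "n_high": len(a),
            "n_low": len(b),
            "mean_high": a.mean() if len(a) else np.nan,
            "se_high": stats.sem(a) if len(a) > 1 else np.nan,
            "mean_low": b.mean() if len(b) else np.nan,
            "se_low": stats.sem(b) if len(b) > 1 else np.nan,
        }
        row["delta"] = row["mean_high"] - row["mean_low"]
        if len(a) > 1 and len(b) > 1 and (a.std() > 0 or b.std() > 0):
            t, p = stats.ttest_ind(a, b, equal_var=False)
        elif len(a) > 1 and len(b) > 1:
            # both samples constant: Welch t degenerates to 0 (no shift)
            # or +/-inf (a pure mean shift with zero variance)
            if np.isclose(row["delta"], 0):
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, row["delta"]), 0.0
        else:
            t, p = np.nan, np.nan
        row["t"] = t
        row["p"] = p
        row["tier"] = tier_from_p(p) if np.isfinite(p) else TIER_NS
        row["low_support"] = len(a) < min_genes or len(b) < min_genes
        rows.append(row)
    tab = pd.DataFrame(rows).set_index("codon")
    finite = tab["p"].notna()
    q = pd.Series(np.nan, index=tab.index)
    if finite.any():
        q[finite] = stats.false_discovery_control(tab.loc[finite, "p"], method="bh")
    tab["bh_q"] = q
    return tab


def select_optimal_codons(
    table: pd.DataFrame,
    candidate_overrides: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Set ``is_optimal`` and ``is_primary`` flags on a deltaRSCU table.

    A codon is optimal when its delta is positive and its tier is strong,
    significant or putative; ``candidate_overrides`` names codons to treat
    as explicitly flagged candidates (tier ``candidate``) despite a
    non-significant P. Per amino acid the primary optimal codon is chosen
    among optimal codons of the best tier present: largest delta, ties by
    smaller P, then alphabetical codon. At most one primary per amino acid.
    """
    tab = table.copy()
    overrides = set(candidate_overrides or ())
    unknown = overrides - set(tab.index)
    if unknown:
        raise KeyError(f"override codons not in table: {sorted(unknown)}")
    tier = tab["tier"].copy()
    for c in overrides:
        if tier[c] == TIER_NS:
            tier[c] = TIER_CANDIDATE
    tab["tier"] = tier
    positive = tab["delta"] > 0
    tab["is_optimal"] = positive & tab["tier"].isin(
        [TIER_STRONG, TIER_SIGNIFICANT, TIER_PUTATIVE, TIER_CANDIDATE]
    )
    tab["is_primary"] = False
    for aa, grp in tab[tab["is_optimal"]].groupby("aa"):
        best_rank = grp["tier"].map(_TIER_RANK).min()
        pool = grp[grp["tier"].map(_TIER_RANK) == best_rank].copy()
        p_col = pool["p"] if "p" in pool else pd.Series(np.nan, index=pool.index)
        pool = pool.assign(_p=p_col.fillna(np.inf))
        pool = pool.sort_values(
            by=["delta", "_p"], ascending=[False, True], kind="mergesort"
        )
        # residual ties broken alphabetically (mergesort keeps index order,
        # which is alphabetical within family by construction)
        tab.loc[pool.index[0], "is_primary"] = True
    return tab


def primary_optimal_set(table: pd.DataFrame) -> frozenset[str]:
    """Codon ids flagged primary in a selected deltaRSCU table."""
    return frozenset(table.index[table["is_primary"]])


def fop(
    codon_counts: Mapping[str, int],
    optimal_set: Iterable[str],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Frequency of optimal codons in one gene.

    Numerator: codons in ``optimal_set``; denominator: codons of amino
    acids that possess an optimal codon (Met/Trp and optimal-less amino
    acids are ignored). NaN when the gene has no eligible codon.
    """
    opts = set(optimal_set)
    if not opts:
        raise ValueError("optimal set is empty")
    eligible_aas = {code.translate(c) for c in opts}
    num = sum(n for c, n in codon_counts.items() if c in opts)
    den = sum(
        n for c, n in codon_counts.items() if code.translate(c) in eligible_aas
    )
    if den == 0:
        return float("nan")
    return num / den


def enc(
    codon_counts: Mapping[str, int], code: GeneticCode = STANDARD_CODE
) -> float:
    """Wright's effective number of codons for one gene.

    Per amino acid with family total m >= 2, the codon homozygosity is
    F = (m * sum(p_i^2) - 1) / (m - 1); ENC = 2 + 9/F2 + 1/F3 + 5/F4 +
    3/F6 with Fk the mean F over observed amino acids of degeneracy k.
    A missing three-fold class (Ile absent) is imputed as the mean of the
    two- and four-fold means; any other missing class leaves ENC
    undefined (NaN). The estimate is clamped to [20, 61].
    """
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa in code.degenerate_amino_acids():
        fam = code.families[aa]
        counts = np.array([codon_counts.get(c, 0) for c in fam], dtype=float)
        m = counts.sum()
        if m < 2:
            continue
        p = counts / m
        f = (m * (p**2).sum() - 1.0) / (m - 1.0)
        f_by_class[len(fam)].append(f)
    means: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_by_class.items() if v
    }
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0
    if not all(k in means for k in (2, 3, 4, 6)):
        return float("nan")
    if any(means[k] <= 0 for k in (2, 3, 4, 6)):
        return 61.0  # homozygosity at its theoretical floor: no usable bias signal
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return float(min(61.0, max(20.0, value)))


def gc3(
    codon_counts: Mapping[str, int],
    include_nondegenerate: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Fraction of counted codons whose third base is G or C.

    By default only codons of degenerate amino acids count (ATG and TGG
    carry no synonymous signal); AT3 is 1 - GC3.
    """
    degenerate = set(_degenerate_codons(code))
    total = 0
    gc = 0
    for c, n in codon_counts.items():
        if code.codon_to_aa.get(c, "*") == "*":
            continue
        if not include_nondegenerate and c not in degenerate:
            continue
        total += n
        if c[2] in "GC":
            gc += n
    if total == 0:
        return float("nan")
    return gc / total


def at3(codon_counts: Mapping[str, int], **kw) -> float:
    return 1.0 - gc3(codon_counts, **kw)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided P.

    Returns (nan, nan) for constant inputs, where the rank correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def mean_abs_delta(table: pd.DataFrame, code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    """Mean and standard error of |delta| over the 59 degenerate-family
    codons of a deltaRSCU table."""
    codons = _degenerate_codons(code)
    missing = [c for c in codons if c not in table.index or not np.isfinite(table.loc[c, "delta"])]
    if missing:
        raise ValueError(f"deltaRSCU missing for codons: {missing}")
    vals = table.loc[codons, "delta"].abs().to_numpy(dtype=float)
    return float(vals.mean()), float(stats.sem(vals))


def compare_distributions(
    a: Sequence[float], b: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Two-sample comparison: Welch t-test (``"t"``) or Mann-Whitney U with
    normal approximation and tie correction (``"mwu"``); two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    if method == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return (0.0, 1.0) if a[0] == b[0] else (float("inf"), 0.0)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if method == "mwu":
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(u), float(p)
    raise ValueError(f"unknown method {method!r}")


_TIER_FROM_STARS = {
    "***": TIER_STRONG,
    "**": TIER_SIGNIFICANT,
    "*": TIER_PUTATIVE,
    "": TIER_NS,
}


def load_table1_fixture(path: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Load the packaged transcription of the published per-species
    deltaRSCU table (59 codons x 3 species, with tier annotations,
    footnote candidate flags and the published primary in ``bold``).

    Returns a dict species -> DataFrame indexed by codon with columns
    ``aa, delta, tier, candidate, bold`` ready for
    :func:`select_optimal_codons` (P values are not printed in the source
    table and are absent).
    """
    if path is None:
        text = resources.files("pancodon.data").joinpath("table1_fixture.tsv").read_text()
    else:
        text = Path(path).read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#", dtype=str)
    out: dict[str, pd.DataFrame] = {}
    for sp in ("gryllus", "oncopeltus", "parhyale"):
        sub = pd.DataFrame(
            {
                "aa": df["aa"].to_numpy(),
                "delta": df[f"{sp}_delta"].astype(float).to_numpy(),
                "tier": df[f"{sp}_stars"].fillna("").map(_TIER_FROM_STARS).to_numpy(),
                "candidate": df[f"{sp}_flag"].fillna("").str.contains("b").to_numpy(),
                "bold": df[f"{sp}_flag"].fillna("").str.contains("p").to_numpy(),
            },
            index=pd.Index(df["codon"], name="codon"),
        )
        out[sp] = sub
    return out


def fixture_candidate_overrides(fixture: Mapping[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Per-species footnote candidate codons recorded in the fixture."""
    return {sp: list(t.index[t["candidate"]]) for sp, t in fixture.items()}
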