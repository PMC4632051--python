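"""Expression normalization (RPM / RPKM) and percentile expression classes.

RPM = reads mapping to a CDS / total reads mapping to all CDS x 1e6.
RPKM additionally divides by CDS length in kb. Genes are assigned to
low / moderate / high classes by the 5th and 95th percentiles of the
chosen metric: the lowest round(0.05*N) genes are "low", the highest
round(0.05*N) are "high", the rest "moderate". Ranking is ascending with
a stable tie-break on gene id so class assignment is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "rpm",
    "rpkm",
    "classify_expression",
    "build_expression_table",
    "read_counts_tsv",
]

logger = logging.getLogger(__name__)

LOW, MODERATE, HIGH = "low", "moderate", "high"


class DegenerateInputError(ValueError):
    """Raised for inputs on which the statistic is undefined."""


def read_counts_tsv(path: str | Path) -> pd.Series:
    """Read a `gene_id<TAB>read_count` table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("counts TSV needs gene_id and read_count columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="read_count")
    if (s < 0).any():
        raise ValueError("negative read counts")
    return s


def rpm(read_counts: pd.Series | Mapping[str, float]) -> pd.Series:
    """Reads per million mapped reads; values sum to 1e6."""
    s = pd.Series(read_counts, dtype=float)
    total = s.sum()
    if total <= 0:
        raise DegenerateInputError("all read counts are zero")
    return s / total * 1_000_000


def rpkm(
    read_counts: pd.Series | Mapping[str, float],
    n_codons: pd.Series | Mapping[str, int],
) -> pd.Series:
    """Reads per kilobase of CDS per million mapped reads.

    CDS length in nt is ``3 * n_codons``.
    """
    counts = pd.Series(read_counts, dtype=float)
    ncod = pd.Series(n_codons, dtype=float).reindex(counts.index)
    if ncod.isna().any():
        missing = list(counts.index[ncod.isna()])[:5]
        raise KeyError(f"genes missing codon counts, e.g. {missing}")
    if (ncod <= 0).any():
        raise DegenerateInputError("zero-length CDS")
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("all read counts are zero")
    length_kb = 3.0 * ncod / 1_000.0
    return counts / (total / 1_000_000.0) / length_kb


def classify_expression(
    values: pd.Series, low_pct: float = 5.0, high_pct: float = 95.0
) -> pd.Series:
    """Assign low/moderate/high classes by percentile rank.

    The tail sizes are ``round(low_pct/100*N)`` and
    ``round((100-high_pct)/100*N)``; ties in ``values`` are broken by gene
    id so the split is reproducible (an all-equal input still yields full
    tails, with a warning).
    """
    n = len(values)
    if n < 20:
        raise DegenerateInputError(f"need >= 20 genes to form 5% tails, got {n}")
    n_low = int(round(low_pct / 100.0 * n))
    n_high = int(round((100.0 - high_pct) / 100.0 * n))
    if values.nunique() == 1:
        logger.warning("all expression values equal; classes set by gene-id order")
    order = values.to_frame("v").reset_index()
    order.columns = ["gene_id", "v"]
    order = order.sort_values(["v", "gene_id"], kind="mergesort")
    cls = pd.Series(MODERATE, index=order["gene_id"], name="expr_class")
    if n_low:
        cls.iloc[:n_low] = LOW
    if n_high:
        cls.iloc[n - n_high :] = HIGH
    return cls.reindex(values.index)


def build_expression_table(
    read_counts: pd.Series,
    n_codons: pd.Series,
    metric: str = "rpm",
    low_pct: float = 5.0,
    high_pct: float = 95.0,
) -> pd.DataFrame:
    """Per-gene table with read_count, rpm, rpkm and expr_class columns.

    ``metric`` chooses which normalization drives the class split.
    """
    if metric not in {"rpm", "rpkm"}:
        raise ValueError(f"unknown expression metric {metric!r}")
    tab = pd.DataFrame({"read_count": read_counts})
    tab["rpm"] = rpm(read_counts)
    tab["rpkm"] = rpkm(read_counts, n_codons)
    tab["expr_class"] = classify_expression(tab[metric], low_pct, high_pct)
    return tab
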