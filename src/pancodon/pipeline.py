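"""End-to-end expression-stratified codon/amino-acid usage analysis.

Composes the library: CDS validation -> expression classes -> per-gene
RSCU -> class-contrast deltaRSCU and optimal-codon selection -> per-gene
Fop/ENC/GC3/composition metrics -> report summaries (class means,
rank correlations, long-gene contrast, degeneracy stratification).
Every summary number is recomputable from the per-gene tables the report
carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import aa_composition, codon_usage, expression
from .cds_io import CdsRecord, Rejection, load_validated_cds
from .codon_model import STANDARD_CODE, GeneticCode, SCScoreTable, load_sc_table
from .expression import HIGH, LOW, MODERATE

__all__ = [
    "AnalysisOptions",
    "AnalysisReport",
    "run_analysis",
    "analyze_records",
    "reference_set_contrast",
    "long_gene_contrast",
    "degeneracy_summary",
    "optimal_codon_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisOptions:
    expression_metric: str = "rpm"
    low_pct: float = 5.0
    high_pct: float = 95.0
    min_genes: int = 10
    length_threshold: int = 500
    candidate_overrides: tuple[str, ...] = ()
    include_nondegenerate_gc3: bool = False
    sc_table: SCScoreTable | None = None


@dataclass
class AnalysisReport:
    gene_metrics: pd.DataFrame  # per gene: n_codons, read_count, rpm, rpkm, expr_class, gc3, at3, enc, fop, fop_bin, pr_high_sc
    delta_rscu: pd.DataFrame  # per codon, with is_optimal / is_primary
    aa_frequencies: pd.DataFrame  # genes x 20
    aa_correlations: pd.DataFrame  # per aa: Spearman R vs Fop
    optimal_summary: dict
    fop_by_class: pd.DataFrame
    gc3_by_class: pd.DataFrame
    correlations: dict  # named Spearman (R, P) pairs
    long_gene_contrast: dict
    degeneracy_summary: pd.DataFrame
    n_rejected: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def primary_optimal_set(self) -> frozenset[str]:
        return codon_usage.primary_optimal_set(self.delta_rscu)


def _class_stats(values: pd.Series, classes: pd.Series) -> pd.DataFrame:
    rows = []
    for cls in (LOW, MODERATE, HIGH):
        v = values[classes == cls].dropna()
        rows.append(
            {
                "expr_class": cls,
                "mean": v.mean() if len(v) else np.nan,
                "se": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                "n": len(v),
            }
        )
    return pd.DataFrame(rows).set_index("expr_class")


def optimal_codon_summary(delta_table: pd.DataFrame) -> dict:
    """Counts of primary optimal codons by ending nucleotide plus the mean
    absolute deltaRSCU over all 59 codons."""
    prim = delta_table[delta_table["is_primary"]]
    mean_abs, se_abs = codon_usage.mean_abs_delta(delta_table)
    return {
        "n_primary": int(len(prim)),
        "n_at_ending": int(sum(c[2] in "AT" for c in prim.index)),
        "n_gc_ending": int(sum(c[2] in "GC" for c in prim.index)),
        "mean_abs_delta": mean_abs,
        "se_abs_delta": se_abs,
    }


def degeneracy_summary(
    delta_table: pd.DataFrame, code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Per degeneracy class, the spread of the primary optimal codons'
    deltaRSCU (classes with no primary are omitted)."""
    prim = delta_table[delta_table["is_primary"]].copy()
    prim["degeneracy"] = prim["aa"].map(code.degeneracy)
    rows = []
    for deg, grp in prim.groupby("degeneracy"):
        rows.append(
            {
                "degeneracy": int(deg),
                "n": len(grp),
                "mean_delta": grp["delta"].mean(),
                "min_delta": grp["delta"].min(),
                "max_delta": grp["delta"].max(),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n", "mean_delta", "min_delta", "max_delta"],
            index=pd.Index([], name="degeneracy"),
        )
    return pd.DataFrame(rows).set_index("degeneracy")


def long_gene_contrast(
    gene_metrics: pd.DataFrame, length_threshold: int = 500
) -> dict:
    """Fop of long genes (> ``length_threshold`` codons) in the high vs low
    expression class, compared by Mann-Whitney U."""
    long_genes = gene_metrics[gene_metrics["n_codons"] > length_threshold]
    hi = long_genes.loc[long_genes["expr_class"] == HIGH, "fop"].dropna()
    lo = long_genes.loc[long_genes["expr_class"] == LOW, "fop"].dropna()
    out: dict = {
        "n_high": int(len(hi)),
        "n_low": int(len(lo)),
        "length_threshold": length_threshold,
    }
    if len(hi) < 2 or len(lo) < 2:
        out.update(
            mean_high=np.nan, se_high=np.nan, mean_low=np.nan, se_low=np.nan,
            mwu_u=np.nan, mwu_p=np.nan, flag="empty-subset",
        )
        return out
    u, p = codon_usage.compare_distributions(hi, lo, method="mwu")
    out.update(
        mean_high=float(hi.mean()),
        se_high=float(hi.std(ddof=1) / np.sqrt(len(hi))),
        mean_low=float(lo.mean()),
        se_low=float(lo.std(ddof=1) / np.sqrt(len(lo))),
        mwu_u=u,
        mwu_p=p,
        flag="",
    )
    return out


def analyze_records(
    records: Sequence[CdsRecord],
    read_counts: pd.Series,
    options: AnalysisOptions = AnalysisOptions(),
) -> AnalysisReport:
    """Run the full analysis on validated CDS records and read counts."""
    if len(records) < 20:
        raise expression.DegenerateInputError(
            f"need >= 20 valid genes, got {len(records)}"
        )
    code = STANDARD_CODE
    sc_table = options.sc_table or load_sc_table()
    by_id = {r.gene_id: r for r in records}
    ids = [r.gene_id for r in records]
    missing = [g for g in ids if g not in read_counts.index]
    if missing:
        logger.warning("%d genes missing read counts; treated as 0", len(missing))
    counts = read_counts.reindex(ids).fillna(0).astype(float)
    n_codons = pd.Series({g: by_id[g].n_codons for g in ids}, name="n_codons")

    expr_tab = expression.build_expression_table(
        counts, n_codons, metric=options.expression_metric,
        low_pct=options.low_pct, high_pct=options.high_pct,
    )
    classes = expr_tab["expr_class"]
    logger.info(
        "expression classes: %s",
        classes.value_counts().to_dict(),
    )

    rscu_all = codon_usage.rscu_matrix(records, code)
    high_ids = classes.index[classes == HIGH]
    low_ids = classes.index[classes == LOW]
    delta = codon_usage.delta_rscu(
        rscu_all.loc[high_ids], rscu_all.loc[low_ids],
        min_genes=options.min_genes, code=code,
    )
    delta = codon_usage.select_optimal_codons(
        delta, candidate_overrides=options.candidate_overrides
    )
    optimal = codon_usage.primary_optimal_set(delta)
    logger.info("selected %d primary optimal codons", len(optimal))

    gm = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    gm["n_codons"] = n_codons
    gm = gm.join(expr_tab)
    gm["gc3"] = [
        codon_usage.gc3(
            by_id[g].codon_counts,
            include_nondegenerate=options.include_nondegenerate_gc3,
            code=code,
        )
        for g in ids
    ]
    gm["at3"] = 1.0 - gm["gc3"]
    gm["enc"] = [codon_usage.enc(by_id[g].codon_counts, code) for g in ids]
    if optimal:
        gm["fop"] = [codon_usage.fop(by_id[g].codon_counts, optimal, code) for g in ids]
    else:
        logger.warning("no optimal codons selected; Fop undefined")
        gm["fop"] = np.nan
    gm["fop_bin"] = [
        aa_composition.bin_fop(f) if np.isfinite(f) else "" for f in gm["fop"]
    ]

    freqs = pd.DataFrame(
        {g: aa_composition.aa_frequencies(by_id[g].codon_counts, code) for g in ids}
    ).T
    freqs.index.name = "gene_id"
    gm["pr_high_sc"] = [
        aa_composition.pr_high_sc(freqs.loc[g], sc_table) for g in ids
    ]

    fop_by_class = _class_stats(gm["fop"], classes)
    gc3_by_class = _class_stats(gm["gc3"], classes)
    hi_gc3 = gm.loc[classes == HIGH, "gc3"].dropna()
    lo_gc3 = gm.loc[classes == LOW, "gc3"].dropna()
    t_stat, t_p = codon_usage.compare_distributions(hi_gc3, lo_gc3, method="t")
    gc3_by_class.attrs["t_high_vs_low"] = {"t": t_stat, "p": t_p}

    def _sp(x: str, y: str) -> tuple[float, float]:
        sub = gm[[x, y]].dropna()
        if len(sub) < 3:
            return (np.nan, np.nan)
        return codon_usage.spearman(sub[x], sub[y])

    correlations = {
        "enc_vs_at3": _sp("enc", "at3"),
        "enc_vs_gc3": _sp("enc", "gc3"),
        "fop_vs_rpm": _sp("fop", "rpm"),
        "fop_vs_at3": _sp("fop", "at3"),
        "fop_vs_gc3": _sp("fop", "gc3"),
        "fop_vs_pr_high_sc": _sp("fop", "pr_high_sc"),
        "gc3_high_vs_low_t": (t_stat, t_p),
    }

    if gm["fop"].notna().sum() >= 3:
        aa_corr = aa_composition.fop_aa_correlations(freqs, gm["fop"])
    else:
        aa_corr = pd.DataFrame(
            {"R": np.nan, "p": np.nan, "n": 0, "sign": "0"},
            index=pd.Index(list(code.amino_acids), name="aa"),
        )

    report = AnalysisReport(
        gene_metrics=gm,
        delta_rscu=delta,
        aa_frequencies=freqs,
        aa_correlations=aa_corr,
        optimal_summary=optimal_codon_summary(delta),
        fop_by_class=fop_by_class,
        gc3_by_class=gc3_by_class,
        correlations=correlations,
        long_gene_contrast=long_gene_contrast(gm, options.length_threshold),
        degeneracy_summary=degeneracy_summary(delta, code),
        metadata={
            "n_genes": len(ids),
            "total_codon_sites": int(n_codons.sum()),
            "expression_metric": options.expression_metric,
        },
    )
    return report


def run_analysis(
    cds_path: str | Path,
    counts_path: str | Path,
    options: AnalysisOptions = AnalysisOptions(),
    exclude_ids: Iterable[str] | None = None,
) -> AnalysisReport:
    """File-level entry point: read + validate CDS, read counts, analyze."""
    records, rejected = load_validated_cds(cds_path, exclude_ids)
    counts = expression.read_counts_tsv(counts_path)
    report = analyze_records(records, counts, options)
    report.n_rejected = len(rejected)
    report.metadata["cds_path"] = str(cds_path)
    report.metadata["counts_path"] = str(counts_path)
    return report


def reference_set_contrast(
    records: Sequence[CdsRecord],
    read_counts: pd.Series,
    reference_ids: Iterable[str],
    options: AnalysisOptions = AnalysisOptions(),
) -> pd.DataFrame:
    """deltaRSCU with the high class replaced by a labeled reference gene
    set (e.g. ribosomal-protein genes), contrasted against the lowest-
    expression class."""
    ref = list(dict.fromkeys(reference_ids))
    if not ref:
        raise ValueError("reference set is empty")
    by_id = {r.gene_id: r for r in records}
    missing = [g for g in ref if g not in by_id]
    if missing:
        raise KeyError(f"reference ids absent from CDS set: {missing}")
    ids = [r.gene_id for r in records]
    counts = read_counts.reindex(ids).fillna(0).astype(float)
    n_codons = pd.Series({g: by_id[g].n_codons for g in ids})
    expr_tab = expression.build_expression_table(
        counts, n_codons, metric=options.expression_metric,
        low_pct=options.low_pct, high_pct=options.high_pct,
    )
    low_ids = expr_tab.index[expr_tab["expr_class"] == LOW]
    rscu_all = codon_usage.rscu_matrix(records)
    delta = codon_usage.delta_rscu(
        rscu_all.loc[ref], rscu_all.loc[low_ids], min_genes=options.min_genes
    )
    return codon_usage.select_optimal_codons(
        delta, candidate_overrides=options.candidate_overrides
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report's tables as TSV plus a JSON summary."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("gene_metrics", report.gene_metrics),
        ("delta_rscu", report.delta_rscu),
        ("aa_correlations", report.aa_correlations),
        ("fop_by_class", report.fop_by_class),
        ("gc3_by_class", report.gc3_by_class),
        ("degeneracy_summary", report.degeneracy_summary),
    ]:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p
    summary = {
        "optimal_summary": report.optimal_summary,
        "correlations": {k: list(v) for k, v in report.correlations.items()},
        "long_gene_contrast": report.long_gene_contrast,
        "metadata": report.metadata,
        "n_rejected": report.n_rejected,
        "primary_optimal_codons": sorted(report.primary_optimal_set),
    }
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    paths["summary"] = p
    return paths
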