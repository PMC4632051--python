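#!/usr/bin/env python
"""Genome-wide optimal-codon usage on the cricket-like simulation: Fop by
expression class, rank correlations (Fop-RPM, Fop-AT3/GC3, ENC-AT3/GC3,
Fop-Pr_HighSC), GC3 contrast between extreme classes, and the long-gene
(>500 codons) Fop robustness check.

Writes per-gene metrics and class summaries under results/genome_wide/."""

import json
from pathlib import Path

from pancodon import pipeline
from pancodon.cds_io import load_validated_cds
from pancodon.expression import read_counts_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "simulated" / "gryllus_like"
OUT = ROOT / "genome_wide"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("run 01_simulate_transcriptomes.py first")
    records, _ = load_validated_cds(SIM / "cds.fasta")
    counts = read_counts_tsv(SIM / "read_counts.tsv")
    report = pipeline.analyze_records(records, counts)
    paths = pipeline.write_report(report, OUT)

    fop = report.fop_by_class["mean"]
    print(
        "Fop by class: low %.3f, moderate %.3f, high %.3f"
        % (fop["low"], fop["moderate"], fop["high"])
    )
    gc3 = report.gc3_by_class["mean"]
    t = report.correlations["gc3_high_vs_low_t"]
    print(
        "GC3 high %.3f vs low %.3f (t = %.1f, P = %.2g): AT3 codons enriched "
        "under high expression" % (gc3["high"], gc3["low"], t[0], t[1])
    )
    for key in ("fop_vs_rpm", "fop_vs_at3", "enc_vs_at3", "fop_vs_pr_high_sc"):
        r, p = report.correlations[key]
        print(f"Spearman {key}: R = {r:+.3f} (P = {p:.2g})")
    lg = report.long_gene_contrast
    print(
        "Long genes (>%d codons): Fop high %.3f +/- %.3f vs low %.3f +/- %.3f "
        "(MWU P = %.2g)"
        % (lg["length_threshold"], lg["mean_high"], lg["se_high"],
           lg["mean_low"], lg["se_low"], lg["mwu_p"])
    )
    print("tables ->", json.dumps({k: str(v) for k, v in paths.items()}, indent=1))


if __name__ == "__main__":
    main()
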