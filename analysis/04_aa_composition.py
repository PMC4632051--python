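#!/usr/bin/env python
"""Expression-linked amino-acid composition on the cricket-like
simulation: Spearman correlations between each amino acid's per-gene
frequency and Fop (the machine twin of a published correlation table),
plus binned-Fop composition means, written under results/aa_composition/."""

from pathlib import Path

from pancodon import aa_composition, pipeline
from pancodon.cds_io import load_validated_cds
from pancodon.expression import read_counts_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "simulated" / "gryllus_like"
OUT = ROOT / "aa_composition"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("run 01_simulate_transcriptomes.py first")
    records, _ = load_validated_cds(SIM / "cds.fasta")
    counts = read_counts_tsv(SIM / "read_counts.tsv")
    report = pipeline.analyze_records(records, counts)
    OUT.mkdir(parents=True, exist_ok=True)
    report.aa_correlations.to_csv(OUT / "fop_aa_correlations.tsv", sep="\t")
    binned = aa_composition.binned_aa_frequencies(
        report.aa_frequencies, report.gene_metrics["fop"]
    )
    binned.to_csv(OUT / "binned_fop_frequencies.tsv", sep="\t", index=False)

    tab = report.aa_correlations
    neg = tab.head(3)
    pos = tab.tail(3)
    print("strongest negative Fop correlations (disfavored under high expression):")
    for aa, row in neg.iterrows():
        print(f"  {aa}: R = {row['R']:+.3f} (P = {row['p']:.2g})")
    print("strongest positive Fop correlations (favored under high expression):")
    for aa, row in pos.iterrows():
        print(f"  {aa}: R = {row['R']:+.3f} (P = {row['p']:.2g})")
    r, p = report.correlations["fop_vs_pr_high_sc"]
    print(f"Pr_HighSC vs Fop: R = {r:+.3f} (P = {p:.2g})")


if __name__ == "__main__":
    main()
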