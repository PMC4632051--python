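#!/usr/bin/env python
"""Generate the four study transcriptomes (AT-rich cricket-like and
milkweed-bug-like, mildly-AT amphipod-like, and a null control), each
2000 genes at 2M-read depth, and write FASTA + read counts + ground
truth under results/simulated/<preset>/."""

from pathlib import Path

from pancodon import simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 7


def main() -> None:
    for name in simulate.PRESET_NAMES:
        cfg = simulate.preset(name, n_genes=2000, seed=SEED)
        sim = simulate.generate_transcriptome(cfg)
        paths = simulate.write_transcriptome(sim, OUT / name)
        total = int(sim.read_counts.sum())
        n_planted = len(sim.truth.planted_optimal)
        print(
            f"{name}: 2000 genes, {total:,} reads, "
            f"{n_planted} planted optimal codons -> {paths['fasta'].parent}"
        )


if __name__ == "__main__":
    main()
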