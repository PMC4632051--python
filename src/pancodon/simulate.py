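"""Synthetic transcriptome generator with planted ground truth.

Emulates the statistical structures the expression-stratified codon
analysis assumes, each with a tunable knob:

* per-gene true expression is log-normal;
* codon choice mixes a background composition (third-position A/T weight
  ``at3_background``) with a planted optimal codon per amino acid, the
  planted mass ``b(e) = b_max * logistic(k * (log e - midpoint))``
  increasing with expression;
* amino-acid composition tilts with expression: gene-level amino-acid
  probabilities are proportional to ``baseline * exp(tilt * z)`` with z
  the cohort-standardized log expression;
* CDS length shrinks with expression,
  ``n_codons = round(exp(alpha - beta*z + eps))`` (floored at 30 codons);
* read counts are Poisson with mean proportional to expression x length,
  scaled to a total depth.

Every emitted CDS starts with ATG, contains no ambiguous base or internal
stop, and ends with a trailing TAA, so it passes the CDS validator by
construction. Output is byte-identical for a given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_model import STANDARD_CODE, GeneticCode

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "SyntheticTranscriptome",
    "generate_transcriptome",
    "preset",
    "PRESET_NAMES",
    "write_transcriptome",
]

# typical globular-protein amino-acid composition, renormalized at use
DEFAULT_AA_BASELINE: dict[str, float] = {
    "A": 0.080, "R": 0.050, "N": 0.042, "D": 0.052, "C": 0.018,
    "Q": 0.040, "E": 0.062, "G": 0.072, "H": 0.022, "I": 0.052,
    "L": 0.090, "K": 0.058, "M": 0.022, "F": 0.040, "P": 0.050,
    "S": 0.068, "T": 0.058, "W": 0.012, "Y": 0.032, "V": 0.066,
}

GRYLLUS_PRIMARIES: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAG",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "TTG", "F": "TTT",
    "P": "CCA", "S": "TCT", "T": "ACT", "Y": "TAT", "V": "GTT",
}
ONCOPELTUS_PRIMARIES: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "E": "GAA",
    "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "Y": "TAT", "V": "GTT",
}
PARHYALE_PRIMARIES: dict[str, str] = {
    "A": "GCC", "N": "AAC", "Q": "CAG", "G": "GGA", "I": "ATC", "L": "CTC",
    "K": "AAG", "F": "TTC", "P": "CCC", "S": "TCG", "T": "ACC", "Y": "TAC",
    "V": "GTC",
}

_GRYLLUS_TILT = {
    "R": -0.15, "T": -0.09, "P": -0.09, "S": -0.08, "A": -0.07, "L": -0.06,
    "G": -0.05, "M": -0.04, "E": 0.15, "D": 0.15, "N": 0.10, "K": 0.09,
    "I": 0.07, "Y": 0.05, "F": 0.03, "V": 0.03, "C": 0.02,
}
_ONCOPELTUS_TILT = {
    "R": -0.15, "G": -0.11, "A": -0.11, "P": -0.09, "L": -0.09, "T": -0.06,
    "M": -0.04, "W": -0.03, "V": -0.03, "S": -0.02,
    "N": 0.16, "K": 0.15, "D": 0.13, "E": 0.12, "I": 0.11, "F": 0.05,
    "Y": 0.04, "C": 0.02,
}
_PARHYALE_TILT = {
    "S": -0.20, "C": -0.07, "T": -0.06, "L": -0.05,
    "D": 0.11, "Y": 0.08, "G": 0.07, "K": 0.07, "E": 0.06, "M": 0.05,
    "Q": 0.04, "F": 0.05, "A": 0.03,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 2000
    seed: int = 0
    log_expr_mean: float = 3.0
    log_expr_sd: float = 2.0
    planted_optimal: Mapping[str, str] = field(default_factory=dict)
    b_max: float = 0.9
    bias_k: float = 1.0
    bias_midpoint: float | None = None  # defaults to log_expr_mean
    at3_background: float = 0.62
    aa_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_BASELINE)
    )
    aa_tilt: Mapping[str, float] = field(default_factory=dict)
    length_alpha: float = math.log(300.0)
    length_beta: float = 0.25
    length_sigma: float = 0.65
    depth: int = 2_000_000
    min_codons: int = 30

    def validate(self) -> None:
        if not 0.0 <= self.b_max <= 1.0:
            raise ValueError(f"b_max must be in [0, 1], got {self.b_max}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.at3_background <= 1.0:
            raise ValueError("at3_background must be a fraction")
        for aa, codon in self.planted_optimal.items():
            if STANDARD_CODE.codon_to_aa.get(codon) != aa:
                raise ValueError(f"planted codon {codon} does not encode {aa}")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    planted_optimal: Mapping[str, str]
    true_expression: Mapping[str, float]
    bias_level: Mapping[str, float]
    n_codons: Mapping[str, int]
    seed: int
    config: Mapping

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class SyntheticTranscriptome:
    sequences: tuple[tuple[str, str], ...]  # (gene_id, CDS incl. trailing stop)
    read_counts: pd.Series
    truth: SyntheticGroundTruth


def _background_codon_probs(
    at3: float, code: GeneticCode = STANDARD_CODE
) -> dict[str, np.ndarray]:
    """Within-family codon probabilities from a third-position A/T weight."""
    out: dict[str, np.ndarray] = {}
    for aa, fam in code.families.items():
        w = np.array([at3 if c[2] in "AT" else 1.0 - at3 for c in fam])
        out[aa] = w / w.sum()
    return out


def generate_transcriptome(config: GeneratorConfig) -> SyntheticTranscriptome:
    """Sample a synthetic transcriptome; deterministic under (config, seed)."""
    config.validate()
    code = STANDARD_CODE
    rng = np.random.default_rng(config.seed)
    aas = list(code.amino_acids)
    baseline = np.array([config.aa_baseline[a] for a in aas], dtype=float)
    baseline = baseline / baseline.sum()
    tilt = np.array([config.aa_tilt.get(a, 0.0) for a in aas], dtype=float)
    background = _background_codon_probs(config.at3_background, code)
    fam_codons = {aa: list(code.families[aa]) for aa in aas}

    log_e = rng.normal(config.log_expr_mean, config.log_expr_sd, config.n_genes)
    sd = log_e.std()
    z = (log_e - log_e.mean()) / (sd if sd > 0 else 1.0)
    mid = config.bias_midpoint if config.bias_midpoint is not None else config.log_expr_mean
    b = config.b_max / (1.0 + np.exp(-config.bias_k * (log_e - mid)))

    eps = rng.normal(0.0, config.length_sigma, config.n_genes)
    n_codons = np.round(
        np.exp(config.length_alpha - config.length_beta * z + eps)
    ).astype(int)
    n_codons = np.maximum(n_codons, config.min_codons)

    width = len(str(config.n_genes))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(config.n_genes)]

    sequences: list[tuple[str, str]] = []
    for g in range(config.n_genes):
        aa_probs = baseline * np.exp(tilt * z[g])
        aa_probs = aa_probs / aa_probs.sum()
        body = rng.choice(len(aas), size=n_codons[g] - 1, p=aa_probs)
        codon_arr = np.empty(n_codons[g] - 1, dtype=object)
        # sample codons per amino acid in one batch; within-gene order is
        # irrelevant to every downstream statistic
        for ai, aa in enumerate(aas):
            pos = np.nonzero(body == ai)[0]
            if len(pos) == 0:
                continue
            fam = fam_codons[aa]
            if len(fam) == 1:
                codon_arr[pos] = fam[0]
                continue
            probs = background[aa]
            planted = config.planted_optimal.get(aa)
            if planted is not None and b[g] > 0:
                probs = (1.0 - b[g]) * probs
                probs[fam.index(planted)] += b[g]
            picks = rng.choice(len(fam), size=len(pos), p=probs)
            for p_i, k in zip(pos, picks):
                codon_arr[p_i] = fam[k]
        sequences.append((gene_ids[g], "ATG" + "".join(codon_arr) + "TAA"))

    expr = np.exp(log_e)
    weight = expr * (3.0 * n_codons)
    lam = config.depth * weight / weight.sum()
    reads = rng.poisson(lam)
    read_counts = pd.Series(reads, index=pd.Index(gene_ids, name="gene_id"), name="read_count")

    truth = SyntheticGroundTruth(
        planted_optimal=dict(config.planted_optimal),
        true_expression={gid: float(e) for gid, e in zip(gene_ids, expr)},
        bias_level={gid: float(x) for gid, x in zip(gene_ids, b)},
        n_codons={gid: int(x) for gid, x in zip(gene_ids, n_codons)},
        seed=config.seed,
        config={
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    )
    return SyntheticTranscriptome(
        sequences=tuple(sequences), read_counts=read_counts, truth=truth
    )


PRESET_NAMES = ("gryllus_like", "oncopeltus_like", "parhyale_like", "null")


def preset(name: str, n_genes: int = 2000, seed: int = 0, depth: int = 2_000_000) -> GeneratorConfig:
    """Fully specified generator configurations.

    ``gryllus_like`` / ``oncopeltus_like``: AT-rich backgrounds (third-
    position A/T weights 0.6177 / 0.6520) with the published 17- and
    16-codon A/T-ending planted sets; ``parhyale_like``: mildly AT-biased
    background (0.5529) with the 13-codon G/C-ending planted set and a
    weaker bias ceiling; ``null``: no planted bias, no tilt, no
    length-expression coupling.
    """
    common = dict(n_genes=n_genes, seed=seed, depth=depth)
    if name == "gryllus_like":
        return GeneratorConfig(
            planted_optimal=GRYLLUS_PRIMARIES,
            at3_background=0.6177,
            aa_tilt=dict(_GRYLLUS_TILT),
            b_max=0.9,
            **common,
        )
    if name == "oncopeltus_like":
        return GeneratorConfig(
            planted_optimal=ONCOPELTUS_PRIMARIES,
            at3_background=0.6520,
            aa_tilt=dict(_ONCOPELTUS_TILT),
            b_max=0.9,
            **common,
        )
    if name == "parhyale_like":
        return GeneratorConfig(
            planted_optimal=PARHYALE_PRIMARIES,
            at3_background=0.5529,
            aa_tilt=dict(_PARHYALE_TILT),
            b_max=0.5,
            **common,
        )
    if name == "null":
        return GeneratorConfig(
            planted_optimal={},
            b_max=0.0,
            aa_tilt={},
            length_beta=0.0,
            **common,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def write_transcriptome(
    sim: SyntheticTranscriptome, out_dir: str | Path, wrap: int = 70
) -> dict[str, Path]:
    """Write FASTA, counts TSV and ground-truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "cds.fasta"
    with open(fasta, "w") as fh:
        for gid, seq in sim.sequences:
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
    counts = out / "read_counts.tsv"
    sim.read_counts.to_csv(counts, sep="\t", header=True)
    truth = out / "ground_truth.json"
    sim.truth.to_json(truth)
    return {"fasta": fasta, "counts": counts, "truth": truth}
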