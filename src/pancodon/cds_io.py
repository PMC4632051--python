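"""Reading and validating coding sequences.

A CDS is accepted when it starts with ATG, has length a multiple of three,
contains only unambiguous bases, and has no internal stop codon. A trailing
stop codon is allowed and is stripped before codon counting (only *internal*
stops are disqualifying). The start ATG is counted as an ordinary Met codon.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .codon_model import STANDARD_CODE, STOP_CODONS

__all__ = [
    "RawRecord",
    "CdsRecord",
    "Rejection",
    "read_cds_fasta",
    "validate_cds",
    "codon_counts",
    "load_validated_cds",
    "write_rejection_report",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RawRecord:
    gene_id: str
    sequence: str


@dataclass(frozen=True)
class CdsRecord:
    """A validated coding sequence with its codon-count vector."""

    gene_id: str
    sequence: str  # trailing stop removed, uppercase DNA
    n_codons: int
    codon_counts: Mapping[str, int]


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    reason: str  # not-multiple-of-3 | no-start-codon | ambiguous-base | internal-stop


def read_cds_fasta(
    path: str | Path, exclude_ids: Iterable[str] | None = None
) -> list[RawRecord]:
    """Parse a (possibly wrapped) CDS FASTA in file order, dropping any
    record whose id appears in ``exclude_ids`` (isoform exclusion)."""
    excluded = set(exclude_ids or ())
    records: list[RawRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in excluded:
            n_dropped += 1
            logger.info("excluding %s (exclusion list)", rec.id)
            continue
        records.append(RawRecord(gene_id=rec.id, sequence=str(rec.seq)))
    if n_dropped:
        logger.info("dropped %d excluded record(s)", n_dropped)
    return records


def validate_cds(raw: RawRecord) -> CdsRecord | Rejection:
    """Apply the CDS inclusion filters; returns a :class:`CdsRecord` or a
    :class:`Rejection` (rejection is a value, not an exception).

    Lowercase is uppercased and U mapped to T before checking.
    """
    seq = raw.sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0 or len(seq) == 0:
        return Rejection(raw.gene_id, "not-multiple-of-3")
    if not seq.startswith("ATG"):
        return Rejection(raw.gene_id, "no-start-codon")
    if set(seq) - _VALID_BASES:
        return Rejection(raw.gene_id, "ambiguous-base")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
        seq = seq[:-3]
    if any(c in STOP_CODONS for c in codons):
        return Rejection(raw.gene_id, "internal-stop")
    counts = dict(Counter(codons))
    return CdsRecord(
        gene_id=raw.gene_id,
        sequence=seq,
        n_codons=len(codons),
        codon_counts=counts,
    )


def codon_counts(record: CdsRecord) -> Mapping[str, int]:
    """Codon-count vector over the 61 sense codons (start ATG included)."""
    return record.codon_counts


def load_validated_cds(
    path: str | Path, exclude_ids: Iterable[str] | None = None
) -> tuple[list[CdsRecord], list[Rejection]]:
    """Read, filter and validate a CDS FASTA; returns (accepted, rejected)."""
    accepted: list[CdsRecord] = []
    rejected: list[Rejection] = []
    for raw in read_cds_fasta(path, exclude_ids):
        out = validate_cds(raw)
        if isinstance(out, CdsRecord):
            accepted.append(out)
        else:
            rejected.append(out)
    logger.info(
        "validated %s: %d accepted, %d rejected", path, len(accepted), len(rejected)
    )
    return accepted, rejected


def write_rejection_report(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for r in rejections:
            fh.write(f"{r.gene_id}\t{r.reason}\n")


def total_codon_sites(records: Iterable[CdsRecord]) -> int:
    """Total codon sites across genes (the genome-wide 'codons examined')."""
    return sum(r.n_codons for r in records)
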