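"""The standard genetic code and amino-acid size/complexity scores.

Synonymous-family structure drives everything downstream: RSCU is defined
within a family, ENC averages family homozygosities by degeneracy class,
and Fop only counts codons of amino acids that have an optimal codon. The
six-fold amino acids (Leu, Ser, Arg) are treated as single six-codon
families throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "GeneticCode",
    "SCScoreTable",
    "STANDARD_CODE",
    "degeneracy_of",
    "sc_score",
    "is_high_sc",
    "load_sc_table",
]

_BASES = "TCAG"

# NCBI translation table 1, indexed TTT, TTC, TTA, TTG, CTT, ...
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class InvalidAminoAcidError(KeyError):
    """Raised when a letter is not one of the 20 standard amino acids."""


def _build_code() -> tuple[dict[str, str], dict[str, list[str]]]:
    codon_to_aa: dict[str, str] = {}
    families: dict[str, list[str]] = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                aa = _AA_ORDER[i]
                i += 1
                codon_to_aa[codon] = aa
                if aa != "*":
                    families.setdefault(aa, []).append(codon)
    for aa in families:
        families[aa].sort()
    return codon_to_aa, dict(sorted(families.items()))


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino-acid mapping plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        All 64 codons; stops map to ``"*"``.
    families
        Amino acid → sorted list of its synonymous codons (61 sense codons
        partitioned into 20 families).
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, a in sorted(self.codon_to_aa.items()) if a != "*")

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def degeneracy(self, aa: str) -> int:
        if aa not in self.families:
            raise InvalidAminoAcidError(aa)
        return len(self.families[aa])

    def degenerate_amino_acids(self) -> tuple[str, ...]:
        """The 18 amino acids with more than one synonymous codon."""
        return tuple(a for a in self.families if len(self.families[a]) > 1)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _standard_code() -> GeneticCode:
    c2a, fams = _build_code()
    return GeneticCode(
        codon_to_aa=c2a,
        families={a: tuple(v) for a, v in fams.items()},
    )


STANDARD_CODE = _standard_code()


def degeneracy_of(aa: str, code: GeneticCode = STANDARD_CODE) -> int:
    """Synonymous-family size of ``aa`` (1, 2, 3, 4 or 6 under the
    standard code)."""
    return code.degeneracy(aa)


@dataclass(frozen=True)
class SCScoreTable:
    """Per-amino-acid size/complexity (S/C) cost scores.

    The S/C score summarizes molecular weight and structural complexity;
    residues scoring above ``high_threshold`` (default 40: Cys, Phe, His,
    Met, Arg, Trp, Tyr) are the "high S/C" class used for Pr_HighSC.
    """

    score: Mapping[str, float]
    high_threshold: float = 40.0

    def __post_init__(self) -> None:
        missing = set(STANDARD_CODE.amino_acids) - set(self.score)
        if missing:
            raise ValueError(f"S/C table missing amino acids: {sorted(missing)}")
        bad = {a: s for a, s in self.score.items() if not s > 0}
        if bad:
            raise ValueError(f"S/C scores must be strictly positive: {bad}")

    def high_sc_set(self) -> frozenset[str]:
        return frozenset(a for a, s in self.score.items() if s > self.high_threshold)


def sc_score(aa: str, table: SCScoreTable) -> float:
    """Return the S/C score of ``aa`` from ``table``."""
    if aa not in table.score:
        raise InvalidAminoAcidError(aa)
    return table.score[aa]


def is_high_sc(aa: str, table: SCScoreTable) -> bool:
    """True iff ``aa`` scores strictly above the table's high-S/C cutoff."""
    return sc_score(aa, table) > table.high_threshold


def load_sc_table(path: str | Path | None = None, high_threshold: float = 40.0) -> SCScoreTable:
    """Load an S/C score table from a two-column TSV (``aa<TAB>score``,
    header required).  With ``path=None`` the packaged default table is used.
    """
    if path is None:
        src = resources.files("pancodon.data").joinpath("sc_scores.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[0].lower() not in {"aa", "amino_acid"}:
        raise ValueError("S/C table must start with a header line 'aa<TAB>score'")
    scores: dict[str, float] = {}
    for ln in lines[1:]:
        aa, val = ln.split("\t")[:2]
        scores[aa.strip()] = float(val)
    return SCScoreTable(score=scores, high_threshold=high_threshold)
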