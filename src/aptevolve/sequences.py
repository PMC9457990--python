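"""DNA sequence primitives shared across the pipeline.

The unit of evolution is a short single-stranded DNA oligonucleotide
(an aptamer candidate), held as a :class:`NucleotideSequence`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# integer encoding used by the folding kernels
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class SequenceError(ValueError):
    """Raised for sequences outside the DNA alphabet or empty input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named single-stranded DNA sequence over {A, C, G, T}.

    Lowercase input is normalised on construction; U, N and other IUPAC
    ambiguity codes are rejected because the thermodynamic model only
    covers the four unmodified deoxynucleotides.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        norm = self.bases.upper()
        if not norm:
            raise SequenceError(f"{self.id!r}: empty sequence")
        bad = set(norm) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"{self.id!r}: invalid characters {sorted(bad)} (DNA A/C/G/T only)"
            )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def encode(self) -> np.ndarray:
        """Integer encoding A=0, C=1, G=2, T=3 (int8)."""
        return np.frombuffer(
            self.bases.encode().translate(
                bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
            ),
            dtype=np.int8,
        ).copy()

    def reverse_complement(self, new_id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            new_id or f"{self.id}_rc", self.bases.translate(_COMPLEMENT)[::-1]
        )

    def gc_fraction(self) -> float:
        return (self.bases.count("G") + self.bases.count("C")) / len(self.bases)


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def read_fasta(path: str | Path) -> List[NucleotideSequence]:
    """Read a multi-record FASTA file into NucleotideSequence objects."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [NucleotideSequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# The parent anti-interferon-gamma aptamer used as the default starting
# point of the maturation loop, and the weakly folding point mutant used
# as its negative control in the docking comparison.
B1_4 = NucleotideSequence(
    "B1-4",
    "CCGCCCAAATCCCTAAGAGAAGACTGTAATGACATCAAACCAGACACACTACACACGCA",
)
NEGATIVE_CONTROL = NucleotideSequence(
    "B1-4-neg",
    "CCGCCCAAATCCCTAAGAGAAGACTATAATGACATCAAACCAGACACACTACACACGCA",
)
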