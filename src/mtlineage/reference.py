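"""Reference mitogenome container and FASTA I/O.

Human mtDNA variants are conventionally reported against the revised
Cambridge Reference Sequence (rCRS), a circular 16,569-bp molecule with
1-based nucleotide positions (nps).  The codec in this package only needs
a reference of that length with the rCRS coordinate conventions; the
packaged default is a deterministic *synthetic* stand-in sequence, not
the real rCRS, suitable for simulation and round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

RCRS_LENGTH = 16569

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceGenome:
    """A named reference sequence with rCRS-style 1-based coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in reference: {sorted(bad)}")
        if "rcrs" in self.name.lower() and len(seq) != RCRS_LENGTH:
            raise ValueError(
                f"an rCRS-style reference must be {RCRS_LENGTH} bp, got {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based np."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"np {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


def synthetic_rcrs(seed: int = 20150214) -> ReferenceGenome:
    """Deterministic synthetic 16,569-bp reference (rCRS stand-in).

    This is NOT the real rCRS; it is a reproducible random sequence of the
    correct length so that every coordinate-level operation (frames that
    wrap the origin, insertion anchors, hotspot nps) behaves exactly as it
    would on the real molecule.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, RCRS_LENGTH)])
    return ReferenceGenome(name="synthetic-rCRS", sequence=seq)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
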