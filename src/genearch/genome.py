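"""Genome sequence container and FASTA access.

Sequences are held in memory as uppercase strings over the alphabet
``A, C, G, T, N``; any other character found in the input is mapped to ``N``.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import gzip
import re
from collections.abc import Mapping
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over ``ACGTN``."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(Mapping):
    """Mapping of chromosome name to nucleotide sequence.

    Lookups outside chromosome bounds raise rather than silently clip, so
    that annotation/genome mismatches surface immediately.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not present in genome") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom[start:end)`` (plus strand).

        Raises ``ValueError`` if the interval is empty, inverted, or falls
        outside the chromosome.
        """
        seq = self[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


def parse_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a FASTA file (optionally gzip-compressed) into a GenomeSequence.

    Sequences are uppercased and non-ACGTN characters replaced by N.
    Duplicate record names are an error.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    seqs: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seqs:
                raise ValueError(f"duplicate FASTA record name: {record.id}")
            seqs[record.id] = _NON_ACGTN.sub("N", str(record.seq).upper())
    return GenomeSequence(seqs)


def write_fasta(sequences: Mapping, path: str | Path, width: int = 60) -> None:
    """Write sequences as plain FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
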