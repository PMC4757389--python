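"""Shared sequence plumbing: complements, the standard genetic code, FASTA/FASTQ I/O.

Format parsing is delegated to Biopython; writing is done directly so that
output is byte-stable under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Fixed 33-nt single-end adapter (TruSeq-style) appended by the simulator
#: and removed by the QC stage.
ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_standard_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_standard_table.forward_table)
for _c in _standard_table.stop_codons:
    CODON_TO_AA[_c] = "*"

STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard_table.stop_codons))

_aa_to_codons: dict[str, list[str]] = {}
for _codon in sorted(_standard_table.forward_table):
    _aa_to_codons.setdefault(_standard_table.forward_table[_codon], []).append(_codon)
#: one-letter amino acid -> synonymous codons (sorted, hence deterministic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {a: tuple(c) for a, c in _aa_to_codons.items()}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single-end sequencing read with per-base phred qualities."""

    id: str
    sequence: str
    qualities: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream phred+33 FASTQ records; malformed records abort with their index."""
    index = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            index += 1
            yield Read(
                rec.id,
                str(rec.seq).upper(),
                list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython's malformed-record error
        raise ValueError(f"malformed FASTQ record near record {index + 1}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write phred+33 FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load FASTA as (id, sequence) pairs, sequences upper-cased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> int:
    n = 0
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


def gc_fraction(sequences: Sequence[str] | str) -> float:
    """(G+C)/(A+C+G+T) over one or many sequences; N is excluded. Errors if no
    counted bases."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no A/C/G/T bases to compute GC content from")
    return gc / (gc + at)
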