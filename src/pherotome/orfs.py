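"""Six-frame ORF extraction with a minimum-length filter.

An ORF here is a maximal stop-free stretch in one of the six reading frames
(not ATG-anchored; 5'-partial ORFs are admitted, with an optional
``require_start`` to anchor at the first Met).  Stretches are emitted when
the encoded protein is at least ``min_aa`` residues (125 by default; the stop
codon is not counted).  Coordinates are 0-based half-open on the forward
strand of the contig and cover the coding residues only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .util import CODON_TO_AA, revcomp

__all__ = ["Contig", "OrfRecord", "translate", "find_orfs", "find_orfs_many"]

MIN_ORF_AA = 125


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A translated ORF located on a contig.

    ``has_start`` is True when the stretch's 5' boundary is delimited by an
    upstream in-frame stop codon (or was anchored at a Met under
    require_start); ``has_stop`` is True when an in-frame stop codon follows.
    Stretches abutting the contig ends carry False flags.
    """

    contig_id: str
    strand: str  # "+" | "-"
    frame: int  # 0 | 1 | 2, on the read strand
    start: int  # forward-strand coordinates, 0-based half-open,
    end: int    # covering the coding residues (stop codon excluded)
    protein: str
    has_start: bool
    has_stop: bool


def translate(nt: str, frame: int = 0, strand: str = "+") -> str:
    """Standard-code translation of one frame; stops render as '*', codons
    containing non-ACGT characters as 'X'."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, or 2")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    seq = nt if strand == "+" else revcomp(nt)
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(out)


def _segments(aa: str) -> Iterable[tuple[int, int, bool, bool]]:
    """Maximal stop-free stretches of a translation, as (start_codon,
    end_codon, preceded_by_stop, followed_by_stop)."""
    start = 0
    for i, c in enumerate(aa):
        if c == "*":
            if i > start:
                yield start, i, start > 0, True
            start = i + 1
    if len(aa) > start:
        yield start, len(aa), start > 0, False


def find_orfs(contig: Contig, min_aa: int = MIN_ORF_AA, require_start: bool = False) -> list[OrfRecord]:
    """All qualifying ORFs of a contig across the six reading frames.

    Output is sorted by (start, end, strand, frame) for reproducibility.
    """
    seq = contig.sequence.upper()
    L = len(seq)
    records: list[OrfRecord] = []
    for strand in "+-":
        read_seq = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            aa = translate(read_seq, frame, "+")
            for a, b, led, stopped in _segments(aa):
                protein = aa[a:b]
                has_start = led
                if require_start:
                    m = protein.find("M")
                    if m < 0:
                        continue
                    a += m
                    protein = protein[m:]
                    has_start = True
                if len(protein) < min_aa:
                    continue
                s, e = frame + 3 * a, frame + 3 * (a + len(protein))
                if strand == "-":
                    s, e = L - e, L - s
                records.append(
                    OrfRecord(contig.id, strand, frame, s, e, protein, has_start, stopped)
                )
    records.sort(key=lambda r: (r.start, r.end, r.strand, r.frame))
    return records


def find_orfs_many(
    contigs: Iterable[Contig], min_aa: int = MIN_ORF_AA, require_start: bool = False
) -> list[OrfRecord]:
    out: list[OrfRecord] = []
    for contig in contigs:
        out.extend(find_orfs(contig, min_aa, require_start))
    return out


def orf_fasta_header(orf: OrfRecord) -> str:
    return f"{orf.contig_id}|{orf.strand}|f{orf.frame}|{orf.start}-{orf.end}"
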