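"""Digital normalization by median k-mer count.

A single streaming pass over the reads: for each read, the median of the
current counts of its canonical k-mers is computed; if the median is below
the coverage cutoff the read is retained and its k-mer counts incremented,
otherwise it is discarded without counting.  With cutoff C this reduces
redundant reads to about C reads per k-mer (exactly C for identical reads,
which see medians 0..C-1 before the cutoff bites).

Counting is exact (a plain hash map) rather than probabilistic; the median
of an even number of values is the lower middle element, matching the
integer "median < cutoff" semantics without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .util import Read, revcomp

__all__ = ["KmerCounter", "canonical_kmers", "normalize_by_median"]


def canonical_kmers(sequence: str, k: int) -> list[str]:
    """In-order canonical k-mers of a sequence.

    Canonical form is the lexicographic minimum of a k-mer and its reverse
    complement; k-mers containing non-ACGT characters are skipped.  A
    sequence shorter than k yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = revcomp(kmer)
        out.append(kmer if kmer <= rc else rc)
    return out


@dataclass
class KmerCounter:
    """Exact canonical k-mer counts."""

    k: int = 20
    counts: dict[str, int] = field(default_factory=dict)

    def add_sequence(self, sequence: str) -> None:
        for kmer in canonical_kmers(sequence, self.k):
            self.counts[kmer] = self.counts.get(kmer, 0) + 1

    def median_count(self, sequence: str) -> int | None:
        """Median (lower middle) of current counts of the sequence's k-mers;
        None if the sequence has no valid k-mer."""
        kmers = canonical_kmers(sequence, self.k)
        if not kmers:
            return None
        values = sorted(self.counts.get(km, 0) for km in kmers)
        return values[(len(values) - 1) // 2]

    def __len__(self) -> int:
        return len(self.counts)


def normalize_by_median(
    reads: Iterable[Read], k: int = 20, cutoff: int = 20
) -> tuple[list[Read], dict]:
    """Single-pass digital normalization; returns (retained reads, report).

    Reads are retained, unmodified and in input order, iff the median count
    of their canonical k-mers is below ``cutoff``; reads with no valid k-mer
    (shorter than k, or all-N) are discarded with a distinct reason.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    counter = KmerCounter(k)
    kept: list[Read] = []
    n_in = n_high = n_short = 0
    for read in reads:
        n_in += 1
        med = counter.median_count(read.sequence)
        if med is None:
            n_short += 1
        elif med < cutoff:
            kept.append(read)
            counter.add_sequence(read.sequence)
        else:
            n_high += 1
    report = {
        "n_input": n_in,
        "n_kept": len(kept),
        "n_discarded_high_coverage": n_high,
        "n_discarded_short": n_short,
        "k": k,
        "cutoff": cutoff,
        "distinct_kmers": len(counter),
    }
    return kept, report
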