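"""Assembly summary statistics: N50, GC content, length distribution."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

from .util import gc_fraction

__all__ = ["n50", "gc_content", "length_histogram", "AssemblyStats", "assembly_stats"]


def n50(lengths: Sequence[int]) -> int:
    """Contig length at which the descending cumulative length first reaches
    half the assembly total."""
    if not lengths:
        raise ValueError("N50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def gc_content(sequences: Sequence[str] | str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator."""
    return gc_fraction(sequences)


def length_histogram(
    lengths: Sequence[int], start: int = 200, width: int = 100, top: int = 5000
) -> list[dict]:
    """Length bins of fixed width from ``start`` up to a final >= ``top`` bin;
    a leading < ``start`` bin keeps the counts summing to the contig total."""
    bins: list[dict] = [{"lo": 0, "hi": start, "count": 0}]
    lo = start
    while lo < top:
        bins.append({"lo": lo, "hi": lo + width, "count": 0})
        lo += width
    bins.append({"lo": top, "hi": None, "count": 0})
    for length in lengths:
        if length < start:
            bins[0]["count"] += 1
        elif length >= top:
            bins[-1]["count"] += 1
        else:
            bins[1 + (length - start) // width]["count"] += 1
    return bins


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    gc_fraction: float
    mean_len: float
    sd_len: float
    n50: int
    length_histogram: list[dict]

    def to_dict(self) -> dict:
        return asdict(self)


def assembly_stats(contigs: Sequence[tuple[str, str]]) -> AssemblyStats:
    """Summary statistics for a set of (id, sequence) contigs."""
    if not contigs:
        raise ValueError("cannot summarize an empty contig set")
    lengths = [len(seq) for _cid, seq in contigs]
    mean = sum(lengths) / len(lengths)
    sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / len(lengths))
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bp=sum(lengths),
        gc_fraction=gc_content([seq for _cid, seq in contigs]),
        mean_len=mean,
        sd_len=sd,
        n50=n50(lengths),
        length_histogram=length_histogram(lengths),
    )
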