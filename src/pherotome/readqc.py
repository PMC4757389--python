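"""Read QC: adapter removal, end quality trimming, and read filtering.

Re-expresses the stated trimming/filtering rules as explicit computation:
bases below Q20 are trimmed from both read ends, reads whose (mean) phred
quality is below 20 are discarded, and reads shorter than 35 bp after
trimming are discarded.  The per-read Q20 statistic is configurable
(mean/median/min); mean is the default, matching average-quality filter
semantics.  Stage order: adapter -> end-trim -> length filter -> quality
filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable

from .util import ADAPTER, Read

__all__ = ["Read", "QcReport", "trim_adapter", "quality_trim_ends", "filter_read", "run_qc"]


@dataclass
class QcReport:
    """Summary of a QC run; counts always reconcile:
    n_input == n_retained + n_discarded_quality + n_discarded_length."""

    n_input: int
    n_discarded_quality: int
    n_discarded_length: int
    n_retained: int
    retained_fraction: float
    mean_retained_length: float
    sd_retained_length: float
    frac_bases_q30: float
    gc_fraction: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def __str__(self) -> str:
        return (
            f"QC: {self.n_retained}/{self.n_input} reads retained "
            f"({100 * self.retained_fraction:.2f}%); "
            f"{self.n_discarded_quality} low quality, "
            f"{self.n_discarded_length} too short; "
            f"mean length {self.mean_retained_length:.2f} "
            f"+/- {self.sd_retained_length:.2f} bp; "
            f"{100 * self.frac_bases_q30:.2f}% of bases >= Q30; "
            f"GC {100 * self.gc_fraction:.2f}%"
        )


def _mismatches(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings; N never matches.
    Stops early once ``limit`` is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x not in "ACGT":
            mm += 1
            if mm > limit:
                break
    return mm


def _scan_adapter(seq: str, adapter: str, min_overlap: int, mismatch_rate: float) -> int | None:
    """Position of the 5'-most qualifying adapter match, or None.

    A match at position i aligns adapter[:o] with seq[i:i+o] where
    o = min(len(seq)-i, len(adapter)); it qualifies if o >= min_overlap and
    the mismatch count is <= floor(mismatch_rate * o).  The 5'-most match is
    the longest 3'-terminal segment removable.
    """
    for i in range(0, len(seq) - min_overlap + 1):
        o = min(len(seq) - i, len(adapter))
        limit = math.floor(mismatch_rate * o)
        if _mismatches(seq[i : i + o], adapter[:o], limit) <= limit:
            return i
    return None


def trim_adapter(
    read: Read, adapter: str, min_overlap: int = 8, mismatch_rate: float = 0.125
) -> Read:
    """Remove 3' adapter contamination (and everything 3' of it).

    The scan is repeated on the remaining prefix until no qualifying match is
    left, so the operation is idempotent.  Qualities are trimmed in lockstep;
    a read with no match is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    seq, quals = read.sequence, read.qualities
    while True:
        hit = _scan_adapter(seq, adapter, min_overlap, mismatch_rate)
        if hit is None:
            break
        seq, quals = seq[:hit], quals[:hit]
    if seq is read.sequence:
        return read
    return Read(read.id, seq, quals)


def quality_trim_ends(read: Read, q_min: int = 20) -> Read:
    """Trim maximal runs of bases with Q < q_min from both read ends."""
    quals = read.qualities
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < q_min:
        lo += 1
    while hi > lo and quals[hi - 1] < q_min:
        hi -= 1
    if lo == 0 and hi == len(quals):
        return read
    return Read(read.id, read.sequence[lo:hi], quals[lo:hi])


_QUALITY_STATS = ("mean", "median", "min")


def _read_quality(read: Read, stat: str) -> float:
    if not read.qualities:
        return 0.0
    if stat == "mean":
        return read.mean_quality()
    if stat == "median":
        q = sorted(read.qualities)
        return float(q[(len(q) - 1) // 2])
    if stat == "min":
        return float(min(read.qualities))
    raise ValueError(f"unknown quality statistic {stat!r}; expected one of {_QUALITY_STATS}")


def filter_read(
    read: Read, q_mean_min: int = 20, len_min: int = 35, quality_stat: str = "mean"
) -> tuple[bool, str | None]:
    """Keep/discard decision for an end-trimmed read.

    Returns (keep, reason) where reason is "length", "quality", or None.
    Length is checked first; boundaries are inclusive (a 35-bp read at mean
    Q20 is kept).
    """
    if len(read) < len_min:
        return False, "length"
    if _read_quality(read, quality_stat) < q_mean_min:
        return False, "quality"
    return True, None


def run_qc(
    reads: Iterable[Read],
    adapter: str = ADAPTER,
    q_trim: int = 20,
    q_mean_min: int = 20,
    len_min: int = 35,
    min_overlap: int = 8,
    mismatch_rate: float = 0.125,
    quality_stat: str = "mean",
) -> tuple[list[Read], QcReport]:
    """Full QC pass: adapter trim, end trim, then length and quality filters.

    Input order is preserved among retained reads.
    """
    retained: list[Read] = []
    n_input = n_len = n_qual = 0
    for read in reads:
        n_input += 1
        read = trim_adapter(read, adapter, min_overlap, mismatch_rate)
        read = quality_trim_ends(read, q_trim)
        keep, reason = filter_read(read, q_mean_min, len_min, quality_stat)
        if keep:
            retained.append(read)
        elif reason == "length":
            n_len += 1
        else:
            n_qual += 1

    lengths = [len(r) for r in retained]
    n_ret = len(retained)
    total_bases = sum(lengths)
    mean_len = total_bases / n_ret if n_ret else 0.0
    sd_len = (
        math.sqrt(sum((x - mean_len) ** 2 for x in lengths) / n_ret) if n_ret else 0.0
    )
    q30 = sum(1 for r in retained for q in r.qualities if q >= 30)
    gc = at = 0
    for r in retained:
        gc += r.sequence.count("G") + r.sequence.count("C")
        at += r.sequence.count("A") + r.sequence.count("T")
    report = QcReport(
        n_input=n_input,
        n_discarded_quality=n_qual,
        n_discarded_length=n_len,
        n_retained=n_ret,
        retained_fraction=n_ret / n_input if n_input else 0.0,
        mean_retained_length=mean_len,
        sd_retained_length=sd_len,
        frac_bases_q30=q30 / total_bases if total_bases else 0.0,
        gc_fraction=gc / (gc + at) if gc + at else 0.0,
    )
    return retained, report
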