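"""Transcript quantification: seed-and-verify read mapping, EM resolution of
multi-mapping reads, TPM with percentile-bootstrap confidence intervals.

The model is deliberately minimal for fixed-length single-end reads: a read
from transcript i occupies one of ell_i = L_i - read_len + 1 start positions
(the effective length, floored at 1), so P(read) = sum over candidate
transcripts of theta_i / ell_i, with theta the transcript count fractions.
EM iterates responsibilities proportional to theta_i / ell_i until the
largest theta change is below 1e-8 (or 1000 iterations).  TPM is
(c_i/ell_i) normalized to sum to 1e6.  Confidence intervals resample reads
with replacement and re-run the EM.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .util import Read, revcomp

__all__ = [
    "effective_length",
    "build_kmer_index",
    "map_reads",
    "em_counts",
    "log_likelihood",
    "tpm",
    "bootstrap_ci",
    "quantify",
    "summarize_expression",
    "tpm_histogram",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000
ACTIVE_TPM = 2.0        # minimal TPM considered biologically active
HIGH_TPM = 100.0        # "highly expressed" threshold


def effective_length(length: int, read_len: int) -> int:
    """Number of distinct read start positions, floored at 1."""
    return max(1, length - read_len + 1)


def _canonical(kmer: str) -> tuple[str, bool]:
    rc = revcomp(kmer)
    return (kmer, True) if kmer <= rc else (rc, False)


def build_kmer_index(
    contigs: Sequence[tuple[str, str]], k: int = 20
) -> dict[str, list[tuple[int, int, bool]]]:
    """Canonical k-mer -> [(contig index, position, canonical-is-forward)]."""
    index: dict[str, list[tuple[int, int, bool]]] = {}
    for ci, (_cid, seq) in enumerate(contigs):
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            canon, fwd = _canonical(kmer)
            index.setdefault(canon, []).append((ci, p, fwd))
    return index


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                break
    return mm


def map_reads(
    reads: Iterable[Read],
    contigs: Sequence[tuple[str, str]],
    seed_k: int = 20,
    max_mismatch: int = 2,
    index: dict | None = None,
) -> tuple[list[frozenset[int]], int]:
    """Candidate contig sets per read (indices into ``contigs``).

    A read is a candidate on every contig where one of its canonical
    ``seed_k``-mers extends to a full-length ungapped alignment with at most
    ``max_mismatch`` substitutions, on either strand.  Returns one (possibly
    empty) frozenset per read, in input order, plus the unmapped count.
    """
    if index is None:
        index = build_kmer_index(contigs, seed_k)
    cand_sets: list[frozenset[int]] = []
    n_unmapped = 0
    for read in reads:
        seq = read.sequence
        rl = len(seq)
        hits: set[int] = set()
        if rl >= seed_k:
            rc_seq = revcomp(seq)
            tried: set[tuple[int, int, bool]] = set()
            for r in range(rl - seed_k + 1):
                kmer = seq[r : r + seed_k]
                if any(c not in "ACGT" for c in kmer):
                    continue
                canon, read_fwd = _canonical(kmer)
                for ci, p, contig_fwd in index.get(canon, ()):
                    if ci in hits:
                        continue
                    if read_fwd == contig_fwd:
                        start = p - r
                        probe = seq
                    else:
                        start = p - (rl - seed_k - r)
                        probe = rc_seq
                    key = (ci, start, read_fwd == contig_fwd)
                    if key in tried:
                        continue
                    tried.add(key)
                    cseq = contigs[ci][1]
                    if start < 0 or start + rl > len(cseq):
                        continue
                    if _count_mismatches(probe, cseq[start : start + rl], max_mismatch) <= max_mismatch:
                        hits.add(ci)
        cand_sets.append(frozenset(hits))
        if not hits:
            n_unmapped += 1
    return cand_sets, n_unmapped


def _em(
    class_counts: dict[frozenset[int], float],
    eff_lens: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> np.ndarray:
    """EM on equivalence classes of reads; returns expected counts per contig."""
    n_contigs = len(eff_lens)
    total = sum(class_counts.values())
    if total == 0:
        return np.zeros(n_contigs)
    classes = [(np.fromiter(c, dtype=int), w) for c, w in class_counts.items() if c]
    theta = np.full(n_contigs, 1.0 / n_contigs)
    counts = np.zeros(n_contigs)
    for _ in range(max_iter):
        counts[:] = 0.0
        for members, weight in classes:
            resp = theta[members] / eff_lens[members]
            denom = resp.sum()
            if denom <= 0:
                resp = np.full(len(members), 1.0 / len(members))
            else:
                resp = resp / denom
            counts[members] += weight * resp
        new_theta = counts / total
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break
    return counts


def em_counts(
    cand_sets: Sequence[frozenset[int]],
    eff_lens: Sequence[float],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> np.ndarray:
    """Expected read counts per contig from per-read candidate sets.

    Empty candidate sets (unmapped reads) are ignored.
    """
    class_counts: dict[frozenset[int], float] = Counter(c for c in cand_sets if c)
    return _em(dict(class_counts), np.asarray(eff_lens, dtype=float), tol, max_iter)


def log_likelihood(
    theta: np.ndarray,
    cand_sets: Sequence[frozenset[int]],
    eff_lens: Sequence[float],
) -> float:
    """Read-level log-likelihood sum(log sum_i theta_i / ell_i) over mapped reads."""
    eff = np.asarray(eff_lens, dtype=float)
    ll = 0.0
    for c in cand_sets:
        if not c:
            continue
        members = np.fromiter(c, dtype=int)
        ll += float(np.log((theta[members] / eff[members]).sum()))
    return ll


def tpm(est_counts: Sequence[float], eff_lens: Sequence[float]) -> np.ndarray:
    """tpm_i = (c_i/ell_i) / sum_j (c_j/ell_j) * 1e6; all-zero counts stay zero."""
    counts = np.asarray(est_counts, dtype=float)
    eff = np.asarray(eff_lens, dtype=float)
    if np.any(eff < 1):
        raise ValueError("effective lengths must be >= 1")
    rate = counts / eff
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


def bootstrap_ci(
    cand_sets: Sequence[frozenset[int]],
    eff_lens: Sequence[float],
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Percentile-bootstrap TPM bounds, shape (n_contigs, 2).

    Reads are resampled with replacement (via a multinomial over equivalence
    classes) and the EM + TPM re-run for each replicate.
    """
    eff = np.asarray(eff_lens, dtype=float)
    mapped = [c for c in cand_sets if c]
    if not mapped:
        return np.zeros((len(eff), 2))
    class_counts = Counter(mapped)
    classes = list(class_counts.keys())
    base = np.array([class_counts[c] for c in classes], dtype=float)
    n = int(base.sum())
    rng = np.random.default_rng(seed)
    tpms = np.empty((n_boot, len(eff)))
    for b in range(n_boot):
        resampled = rng.multinomial(n, base / n)
        counts = _em(dict(zip(classes, resampled.astype(float))), eff)
        tpms[b] = tpm(counts, eff)
    lo = np.percentile(tpms, 100 * alpha / 2, axis=0)
    hi = np.percentile(tpms, 100 * (1 - alpha / 2), axis=0)
    return np.column_stack([lo, hi])


def quantify(
    reads: Iterable[Read],
    contigs: Sequence[tuple[str, str]],
    read_len: int | None = None,
    seed_k: int = 20,
    max_mismatch: int = 2,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Full quantification: map, EM, TPM, bootstrap CIs, ranks and flags.

    ``read_len`` defaults to the most common input read length (used for
    effective lengths).  Returns one row per contig with columns contig_id,
    est_count, eff_len, tpm, ci_low, ci_high, rank, active, highly_expressed.
    """
    reads = list(reads)
    if read_len is None:
        read_len = (
            Counter(len(r) for r in reads).most_common(1)[0][0] if reads else 50
        )
    eff = np.array(
        [effective_length(len(seq), read_len) for _cid, seq in contigs], dtype=float
    )
    cand_sets, _n_unmapped = map_reads(reads, contigs, seed_k, max_mismatch)
    counts = em_counts(cand_sets, eff)
    tpms = tpm(counts, eff)
    if n_boot > 0 and any(c for c in cand_sets):
        ci = bootstrap_ci(cand_sets, eff, n_boot=n_boot, seed=seed)
    else:
        ci = np.zeros((len(contigs), 2))
    df = pd.DataFrame(
        {
            "contig_id": [cid for cid, _seq in contigs],
            "est_count": counts,
            "eff_len": eff,
            "tpm": tpms,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )
    return summarize_expression(df)


def summarize_expression(records: pd.DataFrame) -> pd.DataFrame:
    """Rank by descending TPM (ties broken by contig id) and set activity flags."""
    df = records.copy()
    if df.empty:
        for col in ("rank", "active", "highly_expressed"):
            df[col] = pd.Series(dtype=int if col == "rank" else bool)
        return df
    order = df.sort_values(["tpm", "contig_id"], ascending=[False, True]).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    df["active"] = df["tpm"] >= ACTIVE_TPM
    df["highly_expressed"] = df["tpm"] > HIGH_TPM
    return df.sort_values("rank").reset_index(drop=True)


def tpm_histogram(
    tpms: Sequence[float], unit_max: int = 100, coarse_max: int = 6200, coarse_width: int = 100
) -> list[dict]:
    """Expression histogram: bin width 1 from 0 to ``unit_max``, then width
    ``coarse_width`` from ``unit_max``+1 up to a final >= ``coarse_max`` bin."""
    bins: list[dict] = [
        {"lo": i, "hi": i + 1, "count": 0} for i in range(unit_max + 1)
    ]
    lo = unit_max + 1
    while lo < coarse_max:
        bins.append({"lo": lo, "hi": lo + coarse_width, "count": 0})
        lo += coarse_width
    bins.append({"lo": lo, "hi": None, "count": 0})
    for value in tpms:
        if value < unit_max + 1:
            idx = int(value)
        elif value >= lo:
            idx = len(bins) - 1
        else:
            idx = unit_max + 1 + int((value - (unit_max + 1)) // coarse_width)
        bins[idx]["count"] += 1
    return bins
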