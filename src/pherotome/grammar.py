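"""Three-finger-domain (TFD) pheromone grammar.

Annotates translated ORFs with signal peptides, complete and partial TFDs,
terminal cysteine motifs, and low-complexity tails, then classifies each
protein as one of the salamander courtship-pheromone precursor classes:

* ``alpha_SPF`` — 8-cysteine complete TFD ending XCXXXXCN, followed by a
  6-cysteine partial TFD;
* ``beta_SPF`` — 10-cysteine complete TFD ending CCXXXXCN, followed by an
  8-cysteine partial TFD;
* ``PPS`` — CC-family complete TFD plus a cysteine-free low-complexity
  carboxyl-terminal region (the sodefrin-bearing tail);
* ``PMF`` / ``AFP`` — a single CC-terminal complete TFD with little or no
  tail; the two are separable only by sequence homology, so classification
  accepts an optional homology-derived label for the tie-break;
* ``none`` — anything else (including interleukin-6-family proteins such as
  PRF, which lack the TFD cysteine pattern entirely).

Motif letters are literal cysteine (C) and asparagine (N); X is any residue.
A site matching CC_terminal also matches XC_terminal; CC takes precedence
(the beta/PPS identity hinges on the double cysteine).  Signal peptides are
found with a Kyte-Doolittle hydropathy heuristic plus a (-3,-1) small-residue
cleavage rule — deterministic and adequate for the generator's templates, not
a trained predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from typing import Sequence

__all__ = [
    "MOTIF_PATTERNS",
    "DomainAnnotation",
    "PheromoneCall",
    "match_motif",
    "find_signal_peptide",
    "find_complete_tfds",
    "find_partial_tfd",
    "find_low_complexity_tail",
    "annotate",
    "classify",
]

#: terminal cysteine motifs; length-8 patterns over {C, N, X}
MOTIF_PATTERNS: dict[str, str] = {
    "CC_terminal": "CCXXXXCN",
    "XC_terminal": "XCXXXXCN",
}

#: canonical cysteine count of a complete TFD by terminal-motif family
REQUIRED_CYS = {"CC_terminal": 10, "XC_terminal": 8}

#: extra cysteines tolerated inside a complete-TFD cluster (the anterior SPF
#: TFD is reported with up to twelve cysteines against the canonical ten)
MAX_EXTRA_CYS = 2

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SMALL_RESIDUES = "AGS"  # accepted at the -3 and -1 cleavage positions


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain located on a protein; span is a half-open residue interval."""

    kind: str  # signal_peptide | complete_TFD | partial_TFD | low_complexity_tail
    start: int
    end: int
    cys_positions: tuple[int, ...] = ()
    terminal_motif: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class PheromoneCall:
    orf_id: str
    class_label: str  # alpha_SPF | beta_SPF | PPS | PMF | AFP | none
    completeness: str  # complete | partial
    domains: list[DomainAnnotation] = field(default_factory=list)
    variant_flags: tuple[str, ...] = ()


def match_motif(protein: str, pos: int, pattern: str) -> bool:
    """True iff the length-8 pattern matches at ``pos`` (literal C/N, X free).
    Out-of-range positions never match."""
    if pos < 0 or pos + len(pattern) > len(protein):
        return False
    for offset, letter in enumerate(pattern):
        if letter == "X":
            continue
        if protein[pos + offset] != letter:
            return False
    return True


def _motif_at(protein: str, pos: int) -> str | None:
    """Terminal-motif id matching at pos, CC before XC (CC precedence)."""
    if match_motif(protein, pos, MOTIF_PATTERNS["CC_terminal"]):
        return "CC_terminal"
    if match_motif(protein, pos, MOTIF_PATTERNS["XC_terminal"]):
        return "XC_terminal"
    return None


def find_signal_peptide(
    protein: str,
    max_search: int = 35,
    window: int = 8,
    hydropathy_min: float = 1.5,
    cleavage_range: tuple[int, int] = (15, 30),
) -> DomainAnnotation | None:
    """Detect an amino-terminal signal peptide.

    Reports a signal iff, within the first ``max_search`` residues, some
    ``window``-residue stretch has mean Kyte-Doolittle hydropathy above
    ``hydropathy_min`` and a candidate cleavage site (small residues at -3
    and -1) lies at a position within ``cleavage_range``; the earliest
    qualifying cleavage wins and the hydrophobic window must fit inside the
    signal.  Proteins shorter than 15 residues report none.
    """
    if len(protein) < 15:
        return None
    limit = min(max_search, len(protein))
    means = []
    for w in range(limit - window + 1):
        seg = protein[w : w + window]
        means.append(sum(KYTE_DOOLITTLE.get(c, 0.0) for c in seg) / window)
    lo, hi = cleavage_range
    for c in range(lo, min(hi, len(protein) - 1) + 1):
        if protein[c - 1] in SMALL_RESIDUES and protein[c - 3] in SMALL_RESIDUES:
            if any(m > hydropathy_min for m in means[: max(0, c - window + 1)]):
                return DomainAnnotation("signal_peptide", 0, c)
    return None


def _cluster_back(protein: str, final_cys: int, max_gap: int) -> list[int]:
    """All cysteine positions reachable backwards from ``final_cys`` with
    consecutive gaps <= max_gap (positional difference <= max_gap + 1)."""
    positions = [final_cys]
    i = final_cys - 1
    while i >= 0:
        if protein[i] == "C":
            if positions[-1] - i - 1 > max_gap:
                break
            positions.append(i)
            i -= 1
        else:
            if positions[-1] - i - 1 > max_gap:
                break
            i -= 1
    return positions[::-1]


def find_complete_tfds(
    protein: str,
    max_gap: int = 30,
    span_range: tuple[int, int] = (55, 115),
) -> list[DomainAnnotation]:
    """Annotate complete TFDs: leftmost-first, non-overlapping.

    A complete TFD ends with a CC_terminal or XC_terminal motif and contains,
    counting back from the motif's final cysteine, a cysteine cluster of the
    canonical size (10 for CC, 8 for XC; up to MAX_EXTRA_CYS more tolerated)
    with consecutive-cysteine gaps <= ``max_gap``; its span, from the first
    cluster cysteine to the final motif asparagine, must lie in
    ``span_range``.
    """
    out: list[DomainAnnotation] = []
    i = 0
    n = len(protein)
    lo, hi = span_range
    while i + 8 <= n:
        motif = _motif_at(protein, i)
        if motif is not None:
            final_cys = i + 6
            cluster = _cluster_back(protein, final_cys, max_gap)
            required = REQUIRED_CYS[motif]
            end = i + 8  # final N inclusive -> half-open end
            if required <= len(cluster) <= required + MAX_EXTRA_CYS:
                span = end - cluster[0]
                if lo <= span <= hi:
                    out.append(
                        DomainAnnotation(
                            "complete_TFD", cluster[0], end, tuple(cluster), motif
                        )
                    )
                    i = end
                    continue
        i += 1
    return out


def find_partial_tfd(
    protein: str,
    after: int,
    expected_cys: int,
    max_gap: int = 30,
) -> DomainAnnotation | None:
    """Annotate a downstream cysteine cluster lacking a terminal motif.

    The first cluster of cysteines after ``after`` (consecutive gaps
    <= ``max_gap``) is accepted with ``expected_cys`` cysteines; one fewer is
    tolerated (variant: reduced cysteine count), as are up to MAX_EXTRA_CYS
    more.  A cluster whose region contains a terminal motif match is a
    complete TFD, not a partial one, and yields none.
    """
    if after >= len(protein):
        return None
    positions = [i for i in range(after, len(protein)) if protein[i] == "C"]
    if not positions:
        return None
    cluster = [positions[0]]
    for p in positions[1:]:
        if p - cluster[-1] - 1 > max_gap:
            break
        cluster.append(p)
    if not (expected_cys - 1 <= len(cluster) <= expected_cys + MAX_EXTRA_CYS):
        return None
    start, last = cluster[0], cluster[-1]
    # any terminal motif whose residues intersect the cluster region disqualifies
    for q in range(max(0, start - 7), min(len(protein) - 8, last + 1) + 1):
        if _motif_at(protein, q) is not None:
            return None
    return DomainAnnotation("partial_TFD", start, last + 1, tuple(cluster), None)


def shannon_entropy(text: str) -> float:
    """Shannon entropy (bits/residue) of a string's composition."""
    if not text:
        return 0.0
    freqs = {}
    for c in text:
        freqs[c] = freqs.get(c, 0) + 1
    n = len(text)
    return -sum((v / n) * log2(v / n) for v in freqs.values())


def find_low_complexity_tail(
    protein: str,
    after: int,
    window: int = 12,
    entropy_max_bits: float = 2.9,
    min_len: int = 40,
) -> DomainAnnotation | None:
    """Annotate a cysteine-free low-complexity carboxyl-terminal region.

    Takes the maximal cysteine-free suffix starting at or after ``after``;
    it qualifies if it is at least ``min_len`` residues and its mean windowed
    Shannon entropy is <= ``entropy_max_bits`` (a uniform-random 20-letter
    suffix sits well above that).
    """
    if after >= len(protein):
        return None
    last_c = protein.rfind("C")
    start = max(after, last_c + 1)
    tail = protein[start:]
    if len(tail) < min_len:
        return None
    if len(tail) <= window:
        mean_ent = shannon_entropy(tail)
    else:
        ents = [shannon_entropy(tail[i : i + window]) for i in range(len(tail) - window + 1)]
        mean_ent = sum(ents) / len(ents)
    if mean_ent > entropy_max_bits:
        return None
    return DomainAnnotation("low_complexity_tail", start, len(protein))


def annotate(protein: str, max_gap: int = 30) -> list[DomainAnnotation]:
    """All domain annotations of a protein: signal, complete TFDs, then (from
    the first complete TFD) partial TFD and low-complexity tail."""
    domains: list[DomainAnnotation] = []
    sig = find_signal_peptide(protein)
    if sig:
        domains.append(sig)
    tfds = find_complete_tfds(protein, max_gap=max_gap)
    domains.extend(tfds)
    if tfds:
        first = tfds[0]
        expected = 8 if first.terminal_motif == "CC_terminal" else 6
        partial = find_partial_tfd(protein, first.end, expected, max_gap=max_gap)
        if partial:
            domains.append(partial)
        tail = find_low_complexity_tail(protein, first.end)
        if tail:
            domains.append(tail)
    return domains


def classify(
    orf_id: str,
    protein: str,
    homology_label: str | None = None,
    max_gap: int = 30,
) -> PheromoneCall:
    """Classify a protein into a pheromone precursor class.

    Decision order: (1) CC-terminal complete TFD plus a cysteine-free
    low-complexity tail of >= 40 residues -> PPS; (2) complete TFD plus a
    partial TFD -> beta_SPF if CC-terminal else alpha_SPF; (3) a single
    CC-terminal complete TFD with a carboxyl tail of <= 30 residues -> PMF or
    AFP, disambiguated by ``homology_label`` (without one the call is PMF
    with a ``pmf_afp_ambiguous`` flag); (4) otherwise none.  A tail longer
    than 8 residues in case (3) raises the ``extended_tail`` flag.

    Completeness is ``complete`` iff a signal peptide was detected and the
    class's full domain set is present (guaranteed by the matching branch).
    """
    sig = find_signal_peptide(protein)
    tfds = find_complete_tfds(protein, max_gap=max_gap)
    flags: list[str] = []
    domains: list[DomainAnnotation] = [d for d in (sig,) if d]
    if not tfds:
        return PheromoneCall(orf_id, "none", "partial", domains, ())
    tfd = tfds[0]
    domains.extend(tfds)
    if len(tfd.cys_positions) > REQUIRED_CYS[tfd.terminal_motif]:
        flags.append("extra_cysteine_count")
    cc = tfd.terminal_motif == "CC_terminal"

    tail_ann = find_low_complexity_tail(protein, tfd.end)
    expected_partial = 8 if cc else 6
    partial = find_partial_tfd(protein, tfd.end, expected_partial, max_gap=max_gap)

    label = "none"
    if cc and tail_ann is not None and tail_ann.span >= 40:
        label = "PPS"
        domains.append(tail_ann)
    elif partial is not None:
        label = "beta_SPF" if cc else "alpha_SPF"
        domains.append(partial)
        if len(partial.cys_positions) == expected_partial - 1:
            flags.append("reduced_cysteine_count")
        elif len(partial.cys_positions) > expected_partial:
            flags.append("extra_cysteine_count")
    elif cc and len(protein) - tfd.end <= 30:
        if homology_label in ("PMF", "AFP"):
            label = homology_label
        else:
            label = "PMF"
            flags.append("pmf_afp_ambiguous")
        tail_len = len(protein) - tfd.end
        if 8 < tail_len <= 30:
            flags.append("extended_tail")

    if label == "none":
        return PheromoneCall(orf_id, "none", "partial", domains, tuple(dict.fromkeys(flags)))
    completeness = "complete" if sig is not None else "partial"
    return PheromoneCall(orf_id, label, completeness, domains, tuple(dict.fromkeys(flags)))
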