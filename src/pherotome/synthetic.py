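"""Ground-truth simulator for a pheromone-bearing cloacal-gland transcriptome.

This module generates grammar-conformant pheromone precursor proteins for the
five courtship-pheromone classes of male salamanders (alpha SPF, beta SPF,
PPS, PMF, AFP), decoy transcripts, and simulated 50-bp single-end FASTQ reads
with a per-read ground-truth manifest.  It stands in for the study's raw
sequencing data so that every downstream stage (QC, digital normalization,
ORF extraction, homology filtering, grammar classification, quantification)
can be exercised against a known truth.

Domain layout of a generated precursor, N- to C-terminus::

    [signal peptide][spacer][complete TFD][linker][partial TFD][tail]

where the three-finger domain (TFD) is defined operationally by its cysteine
count, inter-cysteine spacing, and terminal motif (CCXXXXCN for the beta/PPS/
PMF/AFP family, XCXXXXCN for alpha SPF).  Inter-cysteine filler residues are
drawn uniformly from non-Cys, non-Met residues (avoiding spurious motifs and
internal starts); the residue immediately after any cysteine additionally
excludes Asn so no accidental terminal motif can arise.  Spacers use a
hydrophilic alphabet so that a 5'-truncated precursor does not mimic a signal
peptide.  Low-complexity tails are built from a 4-letter alphabet so the
entropy rule is guaranteed to detect them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .util import AA_TO_CODONS, ADAPTER, AMINO_ACIDS, Read, STOP_CODONS

CLASS_LABELS = ("alpha_SPF", "beta_SPF", "PPS", "PMF", "AFP")

# residue alphabets; all exclude C (no cysteines outside declared domains)
# and M (no internal starts)
FILLER_ALPHABET = "ADEFGHIKLNPQRSTVWY"
SPACER_ALPHABET = "DEGHKNPQRST"  # hydrophilic: never looks like a signal core
LOW_COMPLEXITY_ALPHABET = "GPQS"
HYDROPHOBIC_CORE = "FILV"

_LINKER_LEN = 6  # residues between complete-TFD end and partial-TFD cluster


@dataclass(frozen=True)
class GrammarTemplate:
    """Blueprint of a pheromone precursor class.

    ``tfd_gap_range``/``partial_gap_range`` are inclusive bounds on the
    positional difference between consecutive cysteines in the complete and
    partial domains (the residue gap is that difference minus one).
    """

    class_label: str
    signal_len: int
    complete_tfd_cys: int
    complete_tfd_terminal: str  # "CC_terminal" | "XC_terminal"
    partial_tfd_cys: int | None
    tail_len: int
    tail_kind: str  # "low_complexity_cysfree" | "short" | "none"
    spacer_len: int = 10
    tfd_gap_range: tuple[int, int] = (7, 9)
    partial_gap_range: tuple[int, int] = (7, 9)


_DEFAULT_TEMPLATES: dict[str, GrammarTemplate] = {
    # alpha SPF: 18-aa signal, 8-Cys complete TFD ending XCXXXXCN, 6-Cys partial
    "alpha_SPF": GrammarTemplate(
        "alpha_SPF", 18, 8, "XC_terminal", 6, 10, "short",
        spacer_len=10, tfd_gap_range=(8, 10), partial_gap_range=(7, 9),
    ),
    # beta SPF: 18-aa signal, 10-Cys complete TFD ending CCXXXXCN, 8-Cys partial
    "beta_SPF": GrammarTemplate(
        "beta_SPF", 18, 10, "CC_terminal", 8, 10, "short",
        spacer_len=10, tfd_gap_range=(7, 9), partial_gap_range=(6, 9),
    ),
    # PPS: CC-family complete TFD plus a cysteine-free 63-aa low-complexity tail
    "PPS": GrammarTemplate(
        "PPS", 18, 10, "CC_terminal", None, 63, "low_complexity_cysfree",
        spacer_len=10, tfd_gap_range=(7, 9),
    ),
    # PMF: 20-aa signal, one CC-terminal complete TFD, little or no tail.
    # Wider cysteine spacing + spacer keep the precursor above the 125-aa
    # ORF minimum (axolotl PMF-like homologs are longer than canonical PMF).
    "PMF": GrammarTemplate(
        "PMF", 20, 10, "CC_terminal", None, 8, "short",
        spacer_len=20, tfd_gap_range=(10, 12),
    ),
    # AFP: domain structure like PMF; separable only by sequence homology
    "AFP": GrammarTemplate(
        "AFP", 20, 10, "CC_terminal", None, 8, "short",
        spacer_len=20, tfd_gap_range=(10, 12),
    ),
}

# fixed construction seeds for the canonical precursor of each class; the
# reference panel and the default simulator pool share these proteins
_CANONICAL_SEEDS = {"alpha_SPF": 11, "beta_SPF": 12, "PPS": 13, "PMF": 14, "AFP": 15}

# (name, abundance weight, protein length, present in the reference panel)
# weights echo the study's rank structure: structural/housekeeping decoys on
# top, beta SPF and PMF next, alpha/AFP moderate, PPS low
_DECOY_SPECS: tuple[tuple[str, float, int, bool], ...] = (
    ("collagen_like", 6013.0, 210, True),
    ("checkpoint_like", 3950.0, 180, True),
    ("ribosomal_like", 3500.0, 160, True),
    ("mucin_like", 2800.0, 240, True),
    ("ferritin_like", 1800.0, 175, False),
    ("plasminogen_like", 900.0, 220, False),
    ("crisp_like", 600.0, 190, False),
    ("uncharacterized", 300.0, 150, False),
)

DEFAULT_PHEROMONE_WEIGHTS = {
    "beta_SPF": 1476.9,
    "PMF": 1336.2,
    "alpha_SPF": 35.0,
    "AFP": 32.0,
    "PPS": 10.0,
}


def default_template(class_label: str) -> GrammarTemplate:
    """The canonical template for one of the five pheromone classes."""
    try:
        return _DEFAULT_TEMPLATES[class_label]
    except KeyError:
        raise ValueError(
            f"unknown pheromone class {class_label!r}; expected one of {CLASS_LABELS}"
        ) from None


def _choice(rng: np.random.Generator, alphabet: str) -> str:
    return alphabet[int(rng.integers(len(alphabet)))]


def _fill(rng: np.random.Generator, blueprint: Iterable[object]) -> str:
    """Realize a blueprint of literal residues and alphabet draws.

    Elements are either a literal 1-char residue (C/N/M/A...) marked as
    ``("lit", char)`` or an alphabet string to draw from.  A draw immediately
    after a cysteine never yields Asn (prevents accidental terminal motifs).
    """
    out: list[str] = []
    for item in blueprint:
        if isinstance(item, tuple):
            out.append(item[1])
        else:
            alphabet = item
            if out and out[-1] == "C" and "N" in alphabet:
                alphabet = alphabet.replace("N", "")
            out.append(_choice(rng, alphabet))
    return "".join(out)


def _signal_blueprint(signal_len: int) -> list[object]:
    # Met start, hydrophobic core, small residues (Ala) at the -3 and -1
    # positions of the cleavage site so the detector's (-3,-1) rule fires
    # exactly at signal_len and nowhere earlier.
    bp: list[object] = [("lit", "M")]
    for i in range(1, signal_len):
        if i in (signal_len - 3, signal_len - 1):
            bp.append(("lit", "A"))
        else:
            bp.append(HYDROPHOBIC_CORE)
    return bp


def _complete_tfd_blueprint(
    rng: np.random.Generator, n_cys: int, terminal: str, gap_range: tuple[int, int]
) -> list[object]:
    lo, hi = gap_range
    if terminal == "CC_terminal":
        n_lead = n_cys - 3  # motif contributes C,C,...,C
    elif terminal == "XC_terminal":
        n_lead = n_cys - 2  # motif contributes .C,...,C
    else:
        raise ValueError(f"unknown terminal motif {terminal!r}")
    positions = [0]
    # diffs between consecutive cysteines up to the first motif cysteine
    for _ in range(n_lead):
        positions.append(positions[-1] + int(rng.integers(lo, hi + 1)))
    if terminal == "CC_terminal":
        m = positions[-1]  # first motif C
        positions.extend([m + 1, m + 6])
        span = m + 8
    else:
        c7 = positions[-1]  # the motif's X sits at c7 - 1
        positions.append(c7 + 5)
        span = c7 + 7
    cys = set(positions)
    final_n = positions[-1] + 1
    bp: list[object] = []
    for idx in range(span):
        if idx in cys:
            bp.append(("lit", "C"))
        elif idx == final_n:
            bp.append(("lit", "N"))
        else:
            bp.append(FILLER_ALPHABET)
    return bp


def _partial_tfd_blueprint(
    rng: np.random.Generator, n_cys: int, gap_range: tuple[int, int]
) -> list[object]:
    lo, hi = gap_range
    positions = [0]
    for _ in range(n_cys - 1):
        positions.append(positions[-1] + int(rng.integers(lo, hi + 1)))
    cys = set(positions)
    return [("lit", "C") if i in cys else FILLER_ALPHABET for i in range(positions[-1] + 1)]


def make_template_protein(template: GrammarTemplate, seed: int) -> str:
    """Build one precursor protein realizing ``template``; deterministic in seed."""
    if template.class_label not in CLASS_LABELS:
        raise ValueError(
            f"unknown pheromone class {template.class_label!r}; "
            f"expected one of {CLASS_LABELS}"
        )
    if template.signal_len and template.signal_len < 15:
        raise ValueError("signal peptides shorter than 15 residues are not modeled")
    rng = np.random.default_rng(seed)
    bp: list[object] = []
    if template.signal_len:
        bp.extend(_signal_blueprint(template.signal_len))
    bp.extend([SPACER_ALPHABET] * template.spacer_len)
    bp.extend(
        _complete_tfd_blueprint(
            rng,
            template.complete_tfd_cys,
            template.complete_tfd_terminal,
            template.tfd_gap_range,
        )
    )
    if template.partial_tfd_cys:
        bp.extend([FILLER_ALPHABET] * _LINKER_LEN)
        bp.extend(
            _partial_tfd_blueprint(rng, template.partial_tfd_cys, template.partial_gap_range)
        )
    if template.tail_kind == "low_complexity_cysfree":
        bp.extend([LOW_COMPLEXITY_ALPHABET] * template.tail_len)
    elif template.tail_kind == "short":
        bp.extend([SPACER_ALPHABET] * template.tail_len)
    elif template.tail_kind != "none":
        raise ValueError(f"unknown tail kind {template.tail_kind!r}")
    return _fill(rng, bp)


def canonical_protein(class_label: str) -> str:
    """The fixed canonical precursor of a class (shared by pool and panel)."""
    return make_template_protein(default_template(class_label), _CANONICAL_SEEDS[class_label])


def mature_protein(class_label: str) -> str:
    """Canonical precursor with its signal peptide removed (5'-truncated form)."""
    tpl = default_template(class_label)
    return canonical_protein(class_label)[tpl.signal_len :]


def reverse_translate(
    protein: str, seed: int, utr5: int = 0, utr3: int = 0
) -> str:
    """Encode a protein as a CDS with random synonymous codons plus a stop.

    Optional UTR padding is random sequence; a 5' UTR of >= 3 nt ends with an
    in-frame TAA so the CDS is a maximal stop-free stretch in its own frame
    (keeps the simulated ground truth exact for the ORF scanner).
    """
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        if aa not in AA_TO_CODONS:
            raise ValueError(f"non-standard residue {aa!r} cannot be reverse-translated")
        codons.append(AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))])
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    bases = "ACGT"
    five = "".join(_choice(rng, bases) for _ in range(utr5))
    if utr5 >= 3:
        five = five[:-3] + "TAA"
    three = "".join(_choice(rng, bases) for _ in range(utr3))
    return five + "".join(codons) + stop + three


@dataclass(frozen=True)
class TranscriptRecord:
    """One pool member: a pheromone precursor or a decoy transcript."""

    id: str
    class_label: str  # one of CLASS_LABELS or "decoy"
    protein: str
    nucleotide: str
    weight: float


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_choice(rng, AMINO_ACIDS) for _ in range(length))


def canonical_decoy_protein(name: str) -> str:
    """Deterministic decoy protein for a named decoy table entry."""
    for idx, (nm, _w, length, _p) in enumerate(_DECOY_SPECS):
        if nm == name:
            return _random_protein(np.random.default_rng(1000 + idx), length)
    raise ValueError(f"unknown decoy {name!r}")


def make_pool(
    seed: int = 0,
    utr_len: int = 25,
    pheromone_weights: dict[str, float] | None = None,
) -> list[TranscriptRecord]:
    """Default simulation pool: 5 canonical pheromone precursors + 8 decoys.

    Protein sequences are fixed canonical constants; only the nucleotide
    encodings (codon choice, UTRs) vary with ``seed``.
    """
    weights = dict(DEFAULT_PHEROMONE_WEIGHTS)
    if pheromone_weights:
        weights.update(pheromone_weights)
    rng = np.random.default_rng(seed)
    pool: list[TranscriptRecord] = []
    for label in CLASS_LABELS:
        prot = canonical_protein(label)
        nt = reverse_translate(prot, int(rng.integers(2**31)), utr5=utr_len, utr3=utr_len)
        pool.append(TranscriptRecord(f"tx_{label}", label, prot, nt, weights[label]))
    for name, weight, _length, _in_panel in _DECOY_SPECS:
        prot = canonical_decoy_protein(name)
        nt = reverse_translate(prot, int(rng.integers(2**31)), utr5=utr_len, utr3=utr_len)
        pool.append(TranscriptRecord(f"tx_{name}", "decoy", prot, nt, weight))
    return pool


def build_reference_panel() -> list[tuple[str, str]]:
    """The bundled homology reference panel: canonical pheromone templates plus
    housekeeping-style decoy proteins, as (id, protein) pairs."""
    panel = [(f"panel|{label}|template", canonical_protein(label)) for label in CLASS_LABELS]
    panel.extend(
        (f"panel|decoy|{name}", canonical_decoy_protein(name))
        for name, _w, _l, in_panel in _DECOY_SPECS
        if in_panel
    )
    return panel


def pool_manifest(pool: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Per-transcript truth table (id, class_label, weight, length)."""
    return pd.DataFrame(
        {
            "id": [t.id for t in pool],
            "class_label": [t.class_label for t in pool],
            "weight": [t.weight for t in pool],
            "length": [len(t.nucleotide) for t in pool],
        }
    )


def simulate_reads(
    pool: Sequence[TranscriptRecord],
    n_reads: int,
    read_len: int = 50,
    error_model: str = "phred",
    adapter_frac: float = 0.0,
    seed: int = 0,
    mean_quality: float = 34.0,
    sd_quality: float = 4.0,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate single-end reads from a weighted transcript pool.

    Read origins are drawn proportional to weight x (length - read_len + 1);
    positions are uniform over the valid starts (sense strand).  Per-base
    qualities are clamp(round(Normal(mean, sd)), 2, 41); with
    ``error_model="phred"`` each base is substituted with probability
    10^(-Q/10).  A fraction ``adapter_frac`` of reads takes a short insert
    (20..read_len-1 nt) with the fixed 33-nt adapter filling the 3' end.

    Returns the reads and a per-read manifest (read_id, origin_id, position,
    insert_len, n_errors).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    usable = []
    for t in pool:
        if len(t.nucleotide) < read_len:
            warnings.warn(
                f"transcript {t.id} shorter than read length {read_len}; excluded",
                stacklevel=2,
            )
        else:
            usable.append(t)
    if n_reads == 0:
        return [], pd.DataFrame(
            columns=["read_id", "origin_id", "position", "insert_len", "n_errors"]
        )
    if not usable:
        raise ValueError("no transcript is long enough to sample reads from")
    if any(not np.isfinite(t.weight) or t.weight <= 0 for t in usable):
        raise ValueError("abundance weights must be positive and finite")
    probs = np.array(
        [t.weight * (len(t.nucleotide) - read_len + 1) for t in usable], dtype=float
    )
    probs /= probs.sum()
    origins = rng.choice(len(usable), size=n_reads, p=probs)
    bases = "ACGT"
    reads: list[Read] = []
    rows = []
    for i in range(n_reads):
        tx = usable[int(origins[i])]
        n_starts = len(tx.nucleotide) - read_len + 1
        pos = int(rng.integers(n_starts))
        insert_len = read_len
        if adapter_frac > 0 and rng.random() < adapter_frac:
            insert_len = int(rng.integers(max(20, read_len - len(ADAPTER)), read_len))
        seq = tx.nucleotide[pos : pos + insert_len] + ADAPTER[: read_len - insert_len]
        quals = np.clip(
            np.rint(rng.normal(mean_quality, sd_quality, size=read_len)), 2, 41
        ).astype(int)
        n_errors = 0
        if error_model == "phred":
            p_err = 10.0 ** (-quals / 10.0)
            hits = np.nonzero(rng.random(read_len) < p_err)[0]
            if hits.size:
                chars = list(seq)
                for j in hits:
                    alt = bases.replace(chars[j], "") if chars[j] in bases else bases
                    chars[j] = _choice(rng, alt)
                seq = "".join(chars)
                n_errors = int(hits.size)
        elif error_model != "none":
            raise ValueError(f"unknown error model {error_model!r}")
        rid = f"r{i:06d}"
        reads.append(Read(rid, seq, quals.tolist()))
        rows.append((rid, tx.id, pos, insert_len, n_errors))
    manifest = pd.DataFrame(
        rows, columns=["read_id", "origin_id", "position", "insert_len", "n_errors"]
    )
    return reads, manifest


def mutate_protein(
    protein: str, rate: float, seed: int, protect_cys: bool = True
) -> str:
    """Apply random substitutions at ``rate`` per residue; cysteine positions
    are left untouched when ``protect_cys`` (noise model for robustness
    checks, mirroring the conserved TFD cysteine scaffold)."""
    rng = np.random.default_rng(seed)
    chars = list(protein)
    for i, aa in enumerate(chars):
        if protect_cys and aa == "C":
            continue
        if rng.random() < rate:
            chars[i] = _choice(rng, AMINO_ACIDS.replace(aa, ""))
    return "".join(chars)
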