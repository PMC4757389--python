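# Methods

This note documents the models and procedures implemented in `pherotome`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical choices that affect results.

## Read QC (`pherotome.readqc`)

Stages run in fixed order per read: adapter removal, end trimming, length
filter, quality filter.

* **Adapter removal.** The simulator's fixed 33-nt adapter (TruSeq-style) is
  located by scanning every position where a prefix of the adapter aligns to
  the read's 3' end with at least `min_overlap = 8` matched bases and a
  mismatch fraction of at most 0.125 (N never matches).  The 5'-most
  qualifying match — i.e. the longest removable 3' segment — is cut together
  with everything 3' of it, and the scan repeats on the remaining prefix
  until stable.  The repeat makes the whole QC pass idempotent even on
  adversarial inputs where a removal exposes a second spurious match.
* **End trimming.** Maximal runs of bases with Q < 20 are removed from both
  ends; interior bases are never touched (no sliding window).
* **Filters.** Reads shorter than 35 bp are discarded with reason
  `length`; then reads whose per-read quality statistic is below 20 are
  discarded with reason `quality`.  The statistic is the **mean** phred by
  default, matching average-quality filter semantics; `median` and `min` are
  exposed as a config switch because the rule "reads with a phred quality
  score lower than 20" underdetermines the statistic.

The QC report carries input/retained/discarded counts (which always
reconcile), retained length mean +/- SD (population SD), the fraction of
retained bases >= Q30, and GC of retained bases.

## Digital normalization (`pherotome.diginorm`)

One streaming pass in input order.  For each read the median of the current
counts of its canonical k-mers (k = 20) is computed; if the median is below
the cutoff (20) the read is kept and its k-mers counted, otherwise it is
dropped without counting.  Choices:

* **Exact hash counting.**  At desk scale the probabilistic counting used by
  streaming tools is an implementation detail, not part of the method; exact
  counts make the oracle equivalence testable.
* **Median of an even count = lower middle element.**  Counts are integers
  and the retention test is `median < cutoff`; interpolation would blur the
  worked example (100 identical reads at cutoff 20 keep exactly 20: the
  first twenty see medians 0..19).
* Reads with no valid k-mer (shorter than k, or all-N) are discarded with a
  distinct reason.

## ORF extraction (`pherotome.orfs`)

An ORF is a maximal stop-free stretch in one of the six frames, emitted when
its protein is >= 125 residues (stop codon not counted — the threshold is on
coding residues).  ORFs are deliberately **not** ATG-anchored: 5'-partial
ORFs on truncated contigs are part of the biology being classified
downstream (partial pheromone contigs), and `require_start=True` is
available where Met anchoring is wanted.  No coding-potential scoring is
performed; the length filter plus the downstream homology filter stand in
for it, mirroring the workflow being re-expressed.  Coordinates are 0-based
half-open on the forward strand.  `has_start`/`has_stop` record whether the
stretch is delimited by in-frame stops or abuts the contig ends.

## Homology filter (`pherotome.homology`)

Retention = best Smith–Waterman hit against the reference panel with
Karlin–Altschul E <= 1e-5.  (The filter rule as stated — an e-value "of at
least" 1e-5 — plainly intends "at most"; it is implemented as `<=`.)

* Scoring: BLOSUM62, affine gaps with open 11 / extend 1 (a gap of length g
  costs 11 + g).  X and any non-standard residue score 0 against everything.
* E = K·m·n·exp(−λS) with m the query length, n the total panel residue
  count (database-style), and the published gapped BLOSUM62/11/1 parameters
  λ = 0.267, K = 0.041.  Parameters are fixed, not estimated; both are
  config-exposed.  No edge-effect or composition-based correction.
* The original analysis searched three large external protein databases;
  this package substitutes a small bundled panel (the canonical pheromone
  templates plus housekeeping-style decoys) to keep the artifact
  self-contained.  The panel path is configurable, so a real database in
  FASTA form can be dropped in.
* No heuristic seeding (word hits): queries are short enough that the exact
  DP (a numba kernel) is fast.  Traceback prefers diagonal, then
  gap-in-subject, then gap-in-query moves — deterministic spans.

## Pheromone grammar (`pherotome.grammar`)

Motif alphabet: `C` and `N` are literal Cys/Asn, `X` is any residue.  A site
matching `CCXXXXCN` also matches `XCXXXXCN`; CC takes precedence, since the
beta/PPS identity hinges on the double cysteine.

* **Complete TFD**: a terminal-motif match plus, walking back from the
  motif's final cysteine, a cysteine cluster with inter-cysteine gaps of at
  most 30 residues.  Canonical cluster sizes are 10 (CC family) and 8 (XC);
  up to two extra cysteines are tolerated with an `extra_cysteine_count`
  flag, because the anterior SPF domain is described with up to twelve
  cysteines against the canonical ten, and because a substitution creating a
  cysteine should not void an otherwise perfect domain.  The domain span
  (first cluster cysteine to final Asn) must lie in 55–115 residues; scans
  are leftmost-first and non-overlapping.
* **Partial TFD**: the first downstream cysteine cluster with no terminal
  motif anywhere in its region.  Expected sizes are 8 (after a CC domain)
  and 6 (after XC); one missing cysteine is tolerated
  (`reduced_cysteine_count`, matching an observed five-of-six variant), as
  are up to two extra (same rationale as above).
* **Low-complexity tail**: the maximal cysteine-free suffix after the
  complete TFD, accepted when >= 40 residues with mean 12-residue-windowed
  Shannon entropy <= 2.9 bits.  Uniform 20-letter text sits around 3.3–3.5
  bits per 12-residue window, far above the bound; the generator's tails use
  a 4-letter alphabet (<= 2 bits) so detection is guaranteed.
* **Signal peptide**: a heuristic, not a trained model — an 8-residue window
  with mean Kyte–Doolittle hydropathy > 1.5 inside the putative signal, plus
  a cleavage site at position 15–30 with small residues (A/G/S) at −3 and −1.
  The earliest qualifying cleavage wins.  Real-data users should substitute
  external signal-peptide predictions via an annotation side-file; the
  heuristic is deterministic and sufficient for the generator's templates.
* **Decision order**: PPS (CC TFD + qualifying tail) before the SPF pair
  (complete + partial TFD; CC→beta, XC→alpha) before PMF/AFP (single CC TFD,
  tail <= 30; a tail of 9–30 residues raises `extended_tail`, cf. a PMF-like
  contig extended 25 residues beyond the motif).  PMF and AFP share a domain
  structure and are separable only by homology, so `classify` accepts an
  optional homology-derived label; without one the call is PMF with a
  `pmf_afp_ambiguous` flag.  PRF-like (interleukin-6 family) inputs carry no
  TFD scaffold and fall through to `none` by construction.
* Completeness is `complete` iff the signal peptide was detected and the
  class branch matched (each branch requires its full domain set).

## Quantification (`pherotome.quant`)

Model: a read from transcript i occupies one of
`ell_i = max(1, L_i − read_len + 1)` start positions (no fragment-length
distribution — reads are fixed-length single-end, so the full
fragment-model machinery adds nothing).  Mapping is seed-and-verify:
canonical 20-mer seeds, extended to a full-length ungapped alignment with at
most 2 substitutions on either strand (simulator errors are substitutions;
gaps are out of scope).  EM: responsibilities proportional to
`theta_i/ell_i` over each read's candidate set, theta re-estimated as
normalized expected counts, run to `max |Δtheta| < 1e-8` or 1000 iterations
over read equivalence classes.  TPM = `(c_i/ell_i)` normalized to 1e6.

Confidence intervals are a percentile bootstrap (default 100 replicates,
2.5/97.5 percentiles), resampling reads with replacement via a multinomial
over equivalence classes.  The original analysis reports 95% CIs without
describing their construction; the bootstrap is a stated substitute, not a
claim of equivalence.  Ranking is by descending TPM with ties broken by
contig id (reproducible reports); flags: active = TPM >= 2, highly
expressed = TPM > 100.

## Synthetic data (`pherotome.synthetic`)

The generator emulates: 50-bp single-end reads with per-base phred scores
drawn from clamp(round(Normal(34, 4)), 2, 41) — which puts roughly 85–90% of
bases at Q30 or better, echoing the regime of the real libraries —
substitution errors at the per-base phred rate, 3' adapter read-through on a
configurable fraction of reads, and a transcript pool of grammar-conformant
pheromone precursors plus decoys with configurable abundance weights.

* Template layout: signal peptide (Met + hydrophobic core + Ala at the −3/−1
  cleavage positions), hydrophilic spacer, complete TFD, optional linker +
  partial TFD, tail.  Inter-cysteine fillers are uniform over non-Cys,
  non-Met residues, and the residue after a cysteine is never Asn — together
  these guarantee no spurious terminal motif, no extra cysteines, and no
  internal Met start.  Spacers use a hydrophilic alphabet so a 5'-truncated
  precursor cannot mimic a signal peptide.
* Inter-cysteine spacing is drawn per class so domain spans land inside the
  grammar's 55–115 window.  PMF/AFP use wider spacing (10–12) plus a 20-aa
  spacer so their precursors clear the 125-aa ORF minimum — consistent with
  the observation that the axolotl PMF-like homologs have more residues
  between cysteines and are longer than canonical PMF.
* Default abundance weights echo the published expression ranks: beta SPF
  1476.9 and PMF 1336.2 (the two very highly expressed pheromones), alpha
  SPF 35, AFP 32, PPS 10 (no PPS homolog was found in the real gland, but
  the generator must exercise all five grammar classes), with
  collagen/checkpoint/ribosomal/mucin-style decoys above them.  At desk
  scale (13 transcripts vs thousands) only the *rank structure* is
  meaningful; absolute synthetic TPMs are far larger than the published
  per-contig values.
* Reverse translation draws synonymous codons uniformly; a 5' UTR of >= 3 nt
  ends with an in-frame TAA so the CDS is a maximal stop-free stretch in its
  own frame and the simulated ground truth stays exact for the ORF scanner.
* Canonical per-class precursors use fixed construction seeds, shared
  between the simulator pool and the reference panel; all other randomness
  derives from the user seed, and a fixed seed gives byte-identical FASTQ.

Not emulated (hence not demonstrated by passing tests): indels, paired-end
structure, positional/sequence bias, empirical quality profiles, real SPF
sequence composition between cysteines (no published composition to mimic),
and real database search scale.  Recovery results on this generator show
the pipeline's rules are implemented correctly, not that the heuristics
(signal detection especially) match trained predictors on real proteins.

## Problem sizes and statistical design of the checks

The default pipeline run simulates 20,000 reads from 13 transcripts —
enough for every stage to have non-trivial work (QC removes short-insert
adapter reads, normalization compresses ~5x, the EM sees multi-mapped and
unique reads) while a full run takes seconds.  TPM parameter-recovery
checks use pools of 5–6 transcripts at 100x mean coverage with zero error
and a ~4x geometric weight spread: the spread keeps the true-TPM variance
well above multinomial counting noise (so Pearson r >= 0.99 is a property
of the estimator, not luck), while the rarest transcript still receives
several hundred reads (so the 10% per-transcript error bound has margin).
Classifier robustness is measured over 200 precursors at a 2% substitution
rate with cysteines protected, mirroring the conserved cysteine scaffold
against the fast-evolving inter-cysteine regions.

## Known limitations

* The signal-peptide heuristic is tuned to the generator's template family;
  on real proteins it will miss non-canonical signals and should be replaced
  by external predictions.
* Karlin–Altschul parameters are fixed constants; e-values for scoring
  systems other than BLOSUM62/11/1 require re-configuring λ and K.
* The EM has no bias correction and the bootstrap treats reads as i.i.d.;
  both are adequate for the simulator's generative model and untested
  beyond it.
* Digital normalization holds exact k-mer counts in memory; at real
  sequencing scale a counting sketch would be required.
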