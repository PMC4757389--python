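"""End-to-end orchestration of the synthetic pheromone-transcriptome pipeline.

Stage order mirrors the analysed workflow: simulate (or load reads) -> read
QC -> digital normalization -> [contigs supplied; de novo assembly is out of
scope, the simulator's truth set or a user FASTA stands in] -> ORF extraction
-> homology filtering -> grammar classification -> quantification -> summary
report.  Every stage's inputs/outputs are persisted under the output
directory and a manifest records parameters and seeds.  Quantification maps
the QC-filtered (pre-normalization) reads back to the contigs, matching the
workflow being re-expressed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diginorm, grammar, homology, orfs, quant, readqc, report, synthetic, util

logger = logging.getLogger("pherotome")

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "simulate": {
        "n_reads": 20000,
        "read_len": 50,
        "adapter_frac": 0.05,
        "error_model": "phred",
        "utr_len": 25,
    },
    "qc": {"q_trim": 20, "q_mean_min": 20, "len_min": 35, "quality_stat": "mean"},
    "normalize": {"k": 20, "cutoff": 20},
    "orfs": {"min_aa": 125, "require_start": False},
    "homology": {"e_max": 1e-5},
    "quantify": {"seed_k": 20, "max_mismatch": 2, "n_boot": 100},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden section-by-section from a YAML file."""
    config = {section: dict(values) for section, values in DEFAULT_CONFIG.items()}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        for section, values in user.items():
            if section not in config:
                raise ValueError(f"unknown config section {section!r}")
            config[section].update(values or {})
    return config


def _write_json(obj: Any, path: Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def run_pipeline(
    out_dir: str | Path,
    config: dict | str | Path | None = None,
    seed: int = 0,
    reads_path: str | Path | None = None,
    contigs_path: str | Path | None = None,
    panel_path: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full pipeline; returns a dict of in-memory stage results.

    Without ``reads_path``/``contigs_path`` the built-in simulator provides
    both, with ground truth recorded in the output manifest.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (reads_path, contigs_path, panel_path):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict[str, Any] = {"config": config, "seed": seed}
    try:
        _run_stages(out, config, seed, reads_path, contigs_path, panel_path, results)
    finally:
        logger.removeHandler(handler)
        handler.close()
    _write_json(
        {
            "seed": seed,
            "config": config,
            "inputs": {
                "reads": str(reads_path) if reads_path else "simulated",
                "contigs": str(contigs_path) if contigs_path else "simulated",
                "panel": str(panel_path) if panel_path else "bundled",
            },
            "counts": results["counts"],
        },
        out / "run_manifest.json",
    )
    return results


def _run_stages(out, config, seed, reads_path, contigs_path, panel_path, results):
    counts: dict[str, int] = {}
    results["counts"] = counts

    # --- input acquisition -------------------------------------------------
    simulate_cfg = config["simulate"]
    pool = None
    if contigs_path is None or reads_path is None:
        pool = _stage("simulate")(synthetic.make_pool)(
            seed=seed, utr_len=simulate_cfg["utr_len"]
        )
        manifest = synthetic.pool_manifest(pool)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        util.write_fasta([(t.id, t.nucleotide) for t in pool], out / "pool.fasta")
        util.write_fasta([(t.id, t.protein) for t in pool], out / "pool_proteins.fasta")
    if contigs_path is None:
        contigs = [(t.id, t.nucleotide) for t in pool]
    else:
        contigs = _stage("load_contigs")(util.read_fasta)(contigs_path)
    if reads_path is None:
        reads, read_manifest = _stage("simulate")(synthetic.simulate_reads)(
            pool,
            n_reads=simulate_cfg["n_reads"],
            read_len=simulate_cfg["read_len"],
            error_model=simulate_cfg["error_model"],
            adapter_frac=simulate_cfg["adapter_frac"],
            seed=seed,
        )
        util.write_fastq(reads, out / "reads.raw.fastq")
        read_manifest.to_csv(out / "read_manifest.tsv", sep="\t", index=False)
    else:
        reads = list(_stage("load_reads")(util.read_fastq)(reads_path))
    counts["reads_raw"] = len(reads)
    results["pool"] = pool
    results["contigs"] = contigs
    logger.info("input: %d reads, %d contigs", len(reads), len(contigs))

    # --- read QC -----------------------------------------------------------
    qc_cfg = config["qc"]
    qc_reads, qc_report = _stage("qc")(readqc.run_qc)(reads, **qc_cfg)
    util.write_fastq(qc_reads, out / "reads.qc.fastq")
    (out / "qc_report.json").write_text(qc_report.to_json() + "\n")
    counts["reads_qc"] = len(qc_reads)
    results["qc_report"] = qc_report
    logger.info("qc: %s", qc_report)

    # --- digital normalization --------------------------------------------
    norm_cfg = config["normalize"]
    norm_reads, norm_report = _stage("normalize")(diginorm.normalize_by_median)(
        qc_reads, **norm_cfg
    )
    util.write_fastq(norm_reads, out / "reads.norm.fastq")
    _write_json(norm_report, out / "norm_report.json")
    counts["reads_normalized"] = len(norm_reads)
    results["norm_report"] = norm_report
    logger.info("normalize: kept %d/%d reads", norm_report["n_kept"], norm_report["n_input"])

    # --- assembly statistics ----------------------------------------------
    stats = _stage("report")(report.assembly_stats)(contigs)
    _write_json(stats.to_dict(), out / "assembly_stats.json")
    results["assembly_stats"] = stats
    logger.info("assembly: %d contigs, N50 %d bp", stats.n_contigs, stats.n50)

    # --- ORF extraction ----------------------------------------------------
    orf_cfg = config["orfs"]
    orf_records = _stage("orfs")(orfs.find_orfs_many)(
        [orfs.Contig(cid, seq) for cid, seq in contigs], **orf_cfg
    )
    orf_pairs = [(orfs.orf_fasta_header(o), o.protein) for o in orf_records]
    util.write_fasta(orf_pairs, out / "orfs.faa")
    pd.DataFrame(
        [
            (o.contig_id, o.strand, o.frame, o.start, o.end, len(o.protein),
             o.has_start, o.has_stop)
            for o in orf_records
        ],
        columns=["contig_id", "strand", "frame", "start", "end", "aa_len",
                 "has_start", "has_stop"],
    ).to_csv(out / "orfs.tsv", sep="\t", index=False)
    counts["orfs"] = len(orf_records)
    results["orfs"] = orf_records
    logger.info("orfs: %d ORFs >= %d aa", len(orf_records), orf_cfg["min_aa"])

    # --- homology filter ---------------------------------------------------
    panel = (
        util.read_fasta(panel_path) if panel_path else synthetic.build_reference_panel()
    )
    retained_ids, hits = _stage("homology")(homology.filter_by_homology)(
        orf_pairs, panel, e_max=config["homology"]["e_max"]
    )
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    retained_set = set(retained_ids)
    retained_pairs = [(oid, pseq) for oid, pseq in orf_pairs if oid in retained_set]
    util.write_fasta(retained_pairs, out / "orfs.retained.faa")
    counts["orfs_retained"] = len(retained_pairs)
    results["hits"] = hits
    logger.info("homology: retained %d/%d ORFs", len(retained_pairs), len(orf_pairs))

    # --- grammar classification -------------------------------------------
    best_subject = dict(zip(hits["qseqid"], hits["sseqid"]))
    calls = []
    for oid, pseq in retained_pairs:
        subject = best_subject.get(oid, "")
        parts = subject.split("|")
        hom_label = parts[1] if len(parts) == 3 and parts[1] in synthetic.CLASS_LABELS else None
        calls.append(_stage("classify")(grammar.classify)(oid, pseq, homology_label=hom_label))
    calls_df = pd.DataFrame(
        [
            (c.orf_id, c.class_label, c.completeness, ";".join(c.variant_flags))
            for c in calls
        ],
        columns=["orf_id", "class_label", "completeness", "variant_flags"],
    )
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    _write_json(
        [
            {
                "orf_id": c.orf_id,
                "class_label": c.class_label,
                "completeness": c.completeness,
                "variant_flags": list(c.variant_flags),
                "domains": [
                    {
                        "kind": d.kind,
                        "start": d.start,
                        "end": d.end,
                        "n_cys": len(d.cys_positions),
                        "terminal_motif": d.terminal_motif,
                    }
                    for d in c.domains
                ],
            }
            for c in calls
        ],
        out / "calls.json",
    )
    counts["pheromone_calls"] = sum(1 for c in calls if c.class_label != "none")
    results["calls"] = calls
    logger.info("classify: %d pheromone calls", counts["pheromone_calls"])

    # --- quantification ----------------------------------------------------
    quant_cfg = config["quantify"]
    expression = _stage("quantify")(quant.quantify)(
        qc_reads,
        contigs,
        read_len=simulate_cfg["read_len"],
        seed_k=quant_cfg["seed_k"],
        max_mismatch=quant_cfg["max_mismatch"],
        n_boot=quant_cfg["n_boot"],
        seed=seed,
    )
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    _write_json(quant.tpm_histogram(expression["tpm"]), out / "tpm_histogram.json")
    counts["active_contigs"] = int(expression["active"].sum())
    results["expression"] = expression
    logger.info(
        "quantify: %d/%d contigs active (TPM >= 2)",
        counts["active_contigs"], len(expression),
    )

    # --- final report ------------------------------------------------------
    final = {
        "counts": counts,
        "assembly": stats.to_dict(),
        "qc": json.loads(qc_report.to_json()),
        "normalization": norm_report,
        "classification": calls_df.to_dict(orient="records"),
        "top_expression": expression.head(10).to_dict(orient="records"),
    }
    _write_json(final, out / "report.json")
    results["report"] = final
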