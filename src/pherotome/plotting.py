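"""Histogram plots for assembly length and expression distributions."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _bar(bins: Sequence[dict], ax, xlabel: str) -> None:
    labels = [f"{b['lo']}" if b["hi"] is not None else f">={b['lo']}" for b in bins]
    ax.bar(range(len(bins)), [b["count"] for b in bins], width=1.0)
    step = max(1, len(bins) // 10)
    ax.set_xticks(range(0, len(bins), step))
    ax.set_xticklabels(labels[::step], rotation=45, ha="right", fontsize=7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("contigs")


def plot_length_histogram(bins: Sequence[dict], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    _bar(bins, ax, "contig length (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tpm_histogram(bins: Sequence[dict], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    _bar(bins, ax, "expression (TPM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
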