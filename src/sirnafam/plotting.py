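"""Optional matplotlib views of the series tables (stacked bars, size histograms)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def stacked_gene_bars(gene_rpm, path: str | Path) -> None:
    """Per-stage stacked bars of per-gene RPM (one colour per gene)."""
    wide = gene_rpm["rpm"].unstack("gene")
    ax = wide.plot(kind="bar", stacked=True, figsize=(10, 5), width=0.8)
    ax.set_ylabel("RPM")
    ax.set_xlabel("stage")
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()


def size_histograms(size_rpm, path: str | Path) -> None:
    """One panel per stage: RPM by read length, stacked over genes."""
    stages = size_rpm.index.get_level_values("stage").unique()
    n = len(stages)
    ncol = min(5, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, stage in zip(axes.flat, stages):
        wide = size_rpm.loc[stage]["rpm"].unstack("gene")
        wide.plot(kind="bar", stacked=True, ax=ax, legend=False, width=0.9)
        ax.set_title(str(stage), fontsize=9)
        ax.set_xlabel("nt")
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
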