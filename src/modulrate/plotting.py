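"""Minimal diagnostic plots (SVG) for pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _hist(values, observed, title, xlabel, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(values), bins=40, color="0.7")
    ax.axvline(observed, color="crimson", lw=2)
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_phylomorphospace(pms, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    coords = {lab: xy for lab, xy in zip(pms.tip_labels, pms.tip_coords)}
    coords.update({lab: xy for lab, xy in zip(pms.node_labels, pms.node_coords)})
    for parent, child in pms.edges:
        a, b = coords[parent], coords[child]
        ax.plot([a[0], b[0]], [a[1], b[1]], color="0.6", lw=0.7, zorder=1)
    tips = np.asarray(pms.tip_coords)
    ax.scatter(tips[:, 0], tips[:, 1], s=18, color="steelblue", zorder=2)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Phylomorphospace")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def report_plots(report, aligned, space, tree, outdir: Path) -> None:
    res = report.results
    if "modularity" in res:
        _hist(
            res["modularity"]["permuted"], res["modularity"]["cr"],
            "Modularity (CR) permutation null", "CR", outdir / "cr_hist.svg",
        )
    if "integration" in res:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(res["integration"]["scores_left"], res["integration"]["scores_right"], s=18)
        ax.set_xlabel("Block 1 PLS scores")
        ax.set_ylabel("Block 2 PLS scores")
        ax.set_title(f"r-PLS = {res['integration']['r_pls']:.3f}")
        fig.tight_layout()
        fig.savefig(outdir / "pls_scatter.svg")
        plt.close(fig)
    if "rates" in res:
        _hist(
            res["rates"]["null_ratios"], res["rates"]["ratio"],
            "Rate-ratio null (equal rates)", "rate ratio", outdir / "ratio_hist.svg",
        )
    if space is not None and space.scores.shape[1] >= 2:
        from .phylo import phylomorphospace

        pms = phylomorphospace(space.scores[:, :2], list(space.species), tree)
        plot_phylomorphospace(pms, outdir / "phylomorphospace.svg")
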