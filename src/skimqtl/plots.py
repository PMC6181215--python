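"""Figure helpers (matplotlib, Agg-safe). Each function returns the Figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .codes import A, B, UNDET  # noqa: E402


def mosaic_plot(binmap, max_lines: int | None = None):
    """Lines x bins mosaic coloured by parent of origin."""
    g = binmap.genotype if max_lines is None else binmap.genotype[:max_lines]
    img = np.full(g.shape, 0.5)
    img[g == A] = 0.0
    img[g == B] = 1.0
    fig, ax = plt.subplots(figsize=(10, max(2, g.shape[0] * 0.08)))
    ax.imshow(img, aspect="auto", cmap="coolwarm", interpolation="nearest")
    ax.set_xlabel("bin")
    ax.set_ylabel("line")
    fig.tight_layout()
    return fig


def lod_tracks(result, threshold: float | None = None):
    chroms = list(dict.fromkeys(result.table["chrom"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(2.5 * len(chroms), 3),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = result.table[result.table["chrom"] == chrom]
        ax.plot(sub["cm"], sub["lod"], lw=1)
        if threshold is not None:
            ax.axhline(threshold, color="red", ls="--", lw=0.8)
        ax.set_title(f"Chr {chrom}", fontsize=8)
        ax.set_xlabel("cM", fontsize=8)
    axes[0][0].set_ylabel("LOD")
    fig.tight_layout()
    return fig


def manhattan(table, threshold: float | None = None):
    fig, ax = plt.subplots(figsize=(10, 3))
    offset, ticks, labels = 0.0, [], []
    for i, chrom in enumerate(dict.fromkeys(table["chrom"])):
        sub = table[table["chrom"] == chrom]
        x = sub["pos"].to_numpy(dtype=float) + offset
        ax.scatter(x, -np.log10(sub["p_value"]), s=3,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += float(sub["pos"].max())
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    return fig


def qq_plot(p_values):
    p = np.sort(np.asarray(p_values, dtype=float))
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="gray", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    return fig


def correlation_panel(line_means):
    """Pairwise scatter of per-line trait means (columns = traits)."""
    traits = list(line_means.columns)
    k = len(traits)
    fig, axes = plt.subplots(k, k, figsize=(2 * k, 2 * k), squeeze=False)
    for i, ti in enumerate(traits):
        for j, tj in enumerate(traits):
            ax = axes[i][j]
            if i == j:
                ax.hist(line_means[ti], bins=20, color="gray")
            else:
                ax.scatter(line_means[tj], line_means[ti], s=4)
            if i == k - 1:
                ax.set_xlabel(tj, fontsize=8)
            if j == 0:
                ax.set_ylabel(ti, fontsize=8)
    fig.tight_layout()
    return fig
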