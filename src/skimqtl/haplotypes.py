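"""Region-level haplotype clustering and trait-by-haplotype statistics.

Lines from a diversity panel are clustered over a genomic window by
agglomerative clustering on pairwise allele-sharing distance (normalised
Hamming over shared non-missing sites, average linkage by default), and the
resulting groups are compared on a trait by one-way ANOVA plus pairwise
Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .codes import A, B


def extract_region(chroms: np.ndarray, pos: np.ndarray, calls: np.ndarray,
                   chrom: str, start: int, end: int):
    """SNP submatrix for the half-open interval [start, end) on ``chrom``.

    Returns (positions, calls submatrix); raises if the region is empty or
    of non-positive width.
    """
    if end <= start:
        raise ValueError("region must have positive width")
    sel = (np.asarray(chroms) == chrom) & (pos >= start) & (pos < end)
    if not sel.any():
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    return pos[sel], calls[:, sel]


def allele_sharing_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise normalised Hamming distance over shared non-missing sites.

    Calls outside {A, B} count as missing; pairs sharing no informative site
    get the maximal uninformative distance 0.5.
    """
    informative = np.isin(calls, (A, B))
    X = np.where(informative, calls.astype(float), np.nan)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        shared = informative[i] & informative
        diff = (X[i] != X) & shared
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = diff.sum(axis=1) / n_shared
        d[n_shared == 0] = 0.5
        D[i] = d
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


@dataclass
class HaplotypeGrouping:
    region: tuple                      # (chrom, start, end)
    lines: list[str]
    labels: np.ndarray                 # 1..k, canonicalised by first occurrence
    linkage_matrix: np.ndarray
    distance: np.ndarray

    def cluster_sizes(self) -> dict:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node):
            if node.is_leaf():
                return self.lines[node.id]
            return f"({rec(node.left)}:{node.dist / 2:.6g},{rec(node.right)}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (stable under line
    reordering of the distance computation)."""
    mapping, out = {}, np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_haplotypes(calls: np.ndarray, lines: list[str],
                       region: tuple = ("", 0, 0), k: int | None = 2,
                       cut_height: float | None = None,
                       linkage: str = "average") -> HaplotypeGrouping:
    """Hierarchical clustering of lines over a SNP submatrix.

    Either ``k`` (number of clusters) or ``cut_height`` (dendrogram cut) must
    be given.  All-identical lines cannot be split into more than one
    cluster.
    """
    if calls.shape[0] < 2 or calls.shape[1] < 1:
        raise ValueError("need >=2 lines and >=1 SNP")
    D = allele_sharing_distance(calls)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    if cut_height is not None:
        raw = hierarchy.fcluster(Z, cut_height, criterion="distance")
    elif k is not None:
        if k > 1 and np.allclose(D, 0.0):
            raise ValueError("all lines identical in region; cannot form k > 1 clusters")
        raw = hierarchy.fcluster(Z, k, criterion="maxclust")
    else:
        raise ValueError("give k or cut_height")
    labels = _canonical_labels(raw)
    return HaplotypeGrouping(region, list(lines), labels, Z, D)


def subcluster(grouping: HaplotypeGrouping, calls: np.ndarray, cluster: int,
               k: int = 2, linkage: str = "average") -> np.ndarray:
    """Split one cluster further; returns labels like '2.1', '2.2' aligned
    with the parent grouping's lines ('' elsewhere)."""
    mask = grouping.labels == cluster
    sub = cluster_haplotypes(calls[mask], [l for l, m in zip(grouping.lines, mask) if m],
                             grouping.region, k=k, linkage=linkage)
    out = np.array([""] * len(grouping.lines), dtype=object)
    out[mask] = [f"{cluster}.{lab}" for lab in sub.labels]
    return out


def trait_by_haplotype(grouping: HaplotypeGrouping, values: np.ndarray,
                       min_group: int = 2) -> pd.DataFrame:
    """Per-cluster trait summaries plus ANOVA and pairwise Welch t-tests.

    Groups with fewer than ``min_group`` lines are excluded with a warning.
    Returns a summary frame; the ANOVA F/p and the pairwise test table are
    attached as ``.attrs['anova']`` and ``.attrs['pairwise']``.
    """
    values = np.asarray(values, dtype=float)
    groups, labels = [], []
    for lab in np.unique(grouping.labels):
        v = values[(grouping.labels == lab) & ~np.isnan(values)]
        if len(v) < min_group:
            warnings.warn(f"cluster {lab} has {len(v)} lines (<{min_group}); excluded")
            continue
        groups.append(v)
        labels.append(lab)
    if len(groups) < 2:
        raise ValueError("need >=2 clusters with enough lines")
    f_stat, p_anova = stats.f_oneway(*groups)
    summary = pd.DataFrame({
        "cluster": labels,
        "n": [len(v) for v in groups],
        "mean": [float(np.mean(v)) for v in groups],
        "sd": [float(np.std(v, ddof=1)) for v in groups],
    })
    summary["mean_sd"] = [f"{m:.2f} ± {s:.1f}" for m, s in zip(summary["mean"], summary["sd"])]
    pw = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            pw.append({"cluster_a": labels[a], "cluster_b": labels[b],
                       "t_stat": float(t), "p_value": float(p)})
    summary.attrs["anova"] = {"f_stat": float(f_stat), "p_value": float(p_anova)}
    summary.attrs["pairwise"] = pd.DataFrame(pw)
    return summary


def welch_t_from_stats(mean1, sd1, n1, mean2, sd2, n2):
    """Welch t-test from group summaries (unpaired, two-tailed)."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(t), float(p)
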