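"""Genetic-map construction from bin markers.

Markers start in physical (reference) order; adjacent recombination fractions
are estimated from the RIL mosaic, converted to per-meiosis fractions, mapped
to cM with the Kosambi (or Haldane) function, and the order is verified by a
sum-of-adjacent-recombination-fraction (SARF) ripple.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .codes import A, B

MIN_INFORMATIVE = 10


# ---------------------------------------------------------------------------
# map functions

def kosambi(r):
    """Kosambi map distance in cM: d = 25 * ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d):
    """Analytic inverse of :func:`kosambi`: r = tanh(2d/100) / 2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * np.tanh(2.0 * d / 100.0)


def haldane(r):
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_inverse(d):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-d / 50.0))


MAP_FUNCTIONS = {"kosambi": (kosambi, kosambi_inverse),
                 "haldane": (haldane, haldane_inverse)}


# ---------------------------------------------------------------------------
# recombination fractions

def ril_mosaic_to_meiotic(R):
    """Convert the observed RIL mosaic-difference fraction R to the
    per-meiosis recombination fraction for selfed RILs: r = R / (2 - 2R),
    clamped to [0, 0.5)."""
    R = np.asarray(R, dtype=float)
    r = R / (2.0 - 2.0 * R)
    return np.clip(r, 0.0, 0.5 - 1e-9)


def meiotic_to_ril_mosaic(r):
    """Haldane-Waddington expectation for selfed RILs: R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def estimate_rf(codes_i: np.ndarray, codes_j: np.ndarray) -> tuple[float, int, bool]:
    """Per-meiosis recombination fraction between two marker columns.

    Only lines where both markers are parental (A/B) are informative;
    undetermined calls are treated as missing.  Returns (r, n_informative,
    reliable); fewer than ``MIN_INFORMATIVE`` informative lines flags the
    estimate as unreliable.
    """
    ok = np.isin(codes_i, (A, B)) & np.isin(codes_j, (A, B))
    n = int(ok.sum())
    if n == 0:
        return float(0.5 - 1e-9), 0, False
    R = float(np.mean(codes_i[ok] != codes_j[ok]))
    r = float(ril_mosaic_to_meiotic(min(R, 0.5)))
    return r, n, n >= MIN_INFORMATIVE


def rf_matrix(genotype: np.ndarray) -> np.ndarray:
    """Pairwise per-meiosis recombination fractions for a (lines x markers)
    code matrix; used by the ripple."""
    m = genotype.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r, _, _ = estimate_rf(genotype[:, i], genotype[:, j])
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# map

@dataclass
class LinkageMap:
    """Per-chromosome ordered markers with cumulative cM positions."""

    table: pd.DataFrame     # chrom, marker, bp, rf_next, cm
    mapping_function: str = "kosambi"

    @property
    def chrom_names(self) -> list[str]:
        return list(pd.unique(self.table["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.chrom_table(c)["cm"].iloc[-1] for c in self.chrom_names))


def build_linkage_map(markers: pd.DataFrame, genotype: np.ndarray,
                      mapping_function: str = "kosambi") -> LinkageMap:
    """Map from a marker frame (marker, chrom, pos columns, physical order)
    and its (lines x markers) code matrix."""
    to_cm, _ = MAP_FUNCTIONS[mapping_function]
    rows = []
    chroms = markers["chrom"].astype(str).to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cm = 0.0
        for k, i in enumerate(idx):
            if k + 1 < len(idx):
                r, _, reliable = estimate_rf(genotype[:, i], genotype[:, idx[k + 1]])
                rf_next = r
            else:
                rf_next, reliable = np.nan, True
            rows.append({
                "chrom": chrom, "marker": markers["marker"].iloc[i],
                "bp": int(markers["pos"].iloc[i]), "rf_next": rf_next,
                "cm": cm, "reliable": reliable,
            })
            if not np.isnan(rf_next):
                cm += float(to_cm(rf_next))
    return LinkageMap(pd.DataFrame(rows), mapping_function)


def sarf(order: np.ndarray, rf: np.ndarray) -> float:
    """Sum of adjacent recombination fractions for a marker order."""
    return float(rf[order[:-1], order[1:]].sum())


def ripple_check(genotype: np.ndarray, markers: pd.DataFrame, window: int = 3,
                 mapping_function: str = "kosambi") -> tuple[LinkageMap, pd.DataFrame]:
    """Verify (and locally repair) marker order by SARF ripple.

    For every sliding window of ``window`` markers all permutations are
    scored by the sum of adjacent recombination fractions over the whole
    chromosome; a strictly better permutation is applied.  Passes repeat
    until stable.  Returns the rebuilt map plus a report of applied swaps.
    """
    chroms = markers["chrom"].astype(str).to_numpy()
    report = []
    final_order = np.arange(len(markers))
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        rf = rf_matrix(genotype[:, idx])
        order = np.arange(len(idx))
        improved = True
        while improved:
            improved = False
            for s in range(0, len(order) - window + 1):
                best, best_perm = sarf(order, rf), None
                for perm in permutations(range(s, s + window)):
                    cand = order.copy()
                    cand[s:s + window] = order[list(perm)]
                    val = sarf(cand, rf)
                    if val < best - 1e-12:
                        best, best_perm = val, cand
                if best_perm is not None:
                    report.append({"chrom": chrom, "window_start": s,
                                   "old": list(order[s:s + window]),
                                   "new": list(best_perm[s:s + window]),
                                   "sarf": best})
                    order = best_perm
                    improved = True
        final_order[idx] = idx[order]
    reordered = markers.iloc[final_order].reset_index(drop=True)
    lm = build_linkage_map(reordered, genotype[:, final_order], mapping_function)
    return lm, pd.DataFrame(report, columns=["chrom", "window_start", "old", "new", "sarf"])
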