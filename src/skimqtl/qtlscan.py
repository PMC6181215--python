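"""Interval and composite-interval QTL mapping on bin markers.

The scan engine is Haley-Knott regression: at each test position the
expected additive genotype score (A homozygote -> -1, B homozygote -> +1) is
computed from the nearest informative flanking markers via map-function
recombination probabilities for selfed RILs, and the phenotype is regressed
on that score.  LOD = (n/2) * log10(RSS0 / RSS1).  Cofactors (CIM), a
genome-wide permutation threshold, joint-model PVE and a defined two-locus
interaction regression complete the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codes import A, B
from .linkmap import MAP_FUNCTIONS, LinkageMap, meiotic_to_ril_mosaic


# ---------------------------------------------------------------------------
# genotype expectation grid

@dataclass
class ScanGrid:
    """Test positions plus expected genotype scores per line."""

    positions: pd.DataFrame       # chrom, cm, marker (nearest), is_marker
    scores: np.ndarray            # (n_lines, n_positions) in [-1, 1]
    lines: list[str]
    linkage_map: LinkageMap

    def marker_columns(self) -> np.ndarray:
        """Indices of grid positions that sit exactly on a marker."""
        return np.flatnonzero(self.positions["is_marker"].to_numpy())


def _flank_prob_b(score, R):
    """P(Q = B | flanking genotype score, RIL mosaic fraction R)."""
    return 0.5 + score * (0.5 - R)


def scan_grid(lm: LinkageMap, genotype: np.ndarray, lines: list[str],
              step_cm: float = 1.0) -> ScanGrid:
    """Expected genotype scores on a cM grid (markers always included).

    ``genotype`` is the (lines x markers) code matrix aligned with
    ``lm.table`` row order.  Undetermined/missing marker calls are imputed
    from the nearest informative flanking markers; lines with no informative
    marker on a chromosome get score 0 (the prior mean).
    """
    _, inv = MAP_FUNCTIONS[lm.mapping_function]
    tbl = lm.table
    n_lines = genotype.shape[0]
    pos_rows, score_cols = [], []
    for chrom in lm.chrom_names:
        ct = lm.chrom_table(chrom)
        midx = tbl.index[tbl["chrom"] == chrom].to_numpy()
        cm_m = ct["cm"].to_numpy()
        grid = np.unique(np.concatenate([cm_m, np.arange(0.0, cm_m[-1] + 1e-9, step_cm)]))
        is_marker = np.isin(grid, cm_m)
        nearest = np.searchsorted(cm_m, grid)
        nearest = np.clip(nearest, 0, len(cm_m) - 1)
        for p, im, nm in zip(grid, is_marker, nearest):
            pos_rows.append({"chrom": chrom, "cm": float(p),
                             "marker": ct["marker"].iloc[int(nm)], "is_marker": bool(im)})
        sc = np.zeros((n_lines, len(grid)))
        g = genotype[:, midx]
        score_m = np.where(g == B, 1.0, np.where(g == A, -1.0, np.nan))
        for li in range(n_lines):
            inf = np.flatnonzero(~np.isnan(score_m[li]))
            if inf.size == 0:
                continue
            cmi, si = cm_m[inf], score_m[li, inf]
            left = np.searchsorted(cmi, grid, side="right") - 1
            right = left + 1
            has_l, has_r = left >= 0, right < len(cmi)
            x = np.zeros(len(grid))
            both = has_l & has_r
            if both.any():
                Rl = meiotic_to_ril_mosaic(inv(grid[both] - cmi[left[both]]))
                Rr = meiotic_to_ril_mosaic(inv(cmi[right[both]] - grid[both]))
                pb = _flank_prob_b(si[left[both]], Rl) * _flank_prob_b(si[right[both]], Rr)
                pa = (1 - _flank_prob_b(si[left[both]], Rl)) * (1 - _flank_prob_b(si[right[both]], Rr))
                x[both] = (pb - pa) / (pb + pa)
            only_l = has_l & ~has_r
            if only_l.any():
                R = meiotic_to_ril_mosaic(inv(grid[only_l] - cmi[left[only_l]]))
                x[only_l] = si[left[only_l]] * (1 - 2 * R)
            only_r = ~has_l & has_r
            if only_r.any():
                R = meiotic_to_ril_mosaic(inv(cmi[right[only_r]] - grid[only_r]))
                x[only_r] = si[right[only_r]] * (1 - 2 * R)
            sc[li] = x
        score_cols.append(sc)
    positions = pd.DataFrame(pos_rows)
    scores = np.concatenate(score_cols, axis=1)
    return ScanGrid(positions, scores, list(lines), lm)


# ---------------------------------------------------------------------------
# regression core

def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of M on [1 | covariates]."""
    n = M.shape[0]
    D = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(D)
    return M - Q @ (Q.T @ M)


def scan_core(X: np.ndarray, Y: np.ndarray, covariates: np.ndarray | None = None):
    """Vectorised single-locus regression of phenotype(s) on score columns.

    X: (n, P) genotype scores; Y: (n,) or (n, m) phenotypes.  Returns
    (lod, beta, r2) each of shape (P,) or (P, m).  Monomorphic columns give
    lod = beta = r2 = 0.
    """
    y2d = np.atleast_2d(Y.T).T
    n = X.shape[0]
    n_fixed = 1 + (0 if covariates is None else covariates.shape[1])
    if n <= n_fixed + 1:
        raise ValueError("too few lines for the requested model")
    Xr = _residualize(X, covariates)
    Yr = _residualize(y2d, covariates)
    rss0 = np.sum(Yr ** 2, axis=0)                    # (m,)
    sxx = np.sum(Xr ** 2, axis=0)                     # (P,)
    sxy = Xr.T @ Yr                                   # (P, m)
    ok = sxx > 1e-12
    beta = np.zeros_like(sxy)
    beta[ok] = sxy[ok] / sxx[ok, None]
    rss1 = np.maximum(rss0[None, :] - beta * sxy, 1e-300)
    with np.errstate(divide="ignore"):
        lod = np.where(rss0[None, :] > 0, (n / 2.0) * np.log10(rss0[None, :] / rss1), 0.0)
    r2 = np.where(rss0[None, :] > 0, 1.0 - rss1 / rss0[None, :], 0.0)
    lod[~ok] = 0.0
    r2[~ok] = 0.0
    if Y.ndim == 1:
        return lod[:, 0], beta[:, 0], r2[:, 0]
    return lod, beta, r2


# ---------------------------------------------------------------------------
# results

@dataclass
class ScanResult:
    trait: str
    environment: str | None
    table: pd.DataFrame           # chrom, cm, marker, lod, additive, r2
    threshold: float | None = None
    cofactors: list | None = None

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peaks(self, threshold: float | None = None) -> pd.DataFrame:
        """One peak per contiguous above-threshold segment per chromosome."""
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no threshold available")
        rows = []
        for chrom in pd.unique(self.table["chrom"]):
            sub = self.table[self.table["chrom"] == chrom].reset_index(drop=True)
            above = (sub["lod"] >= thr).to_numpy()
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                seg = sub.iloc[s:e]
                top = seg.loc[seg["lod"].idxmax()]
                rows.append({"trait": self.trait, "environment": self.environment,
                             "chrom": chrom, "cm": top["cm"], "marker": top["marker"],
                             "lod": top["lod"], "additive": top["additive"],
                             "pve": 100.0 * top["r2"]})
        return pd.DataFrame(rows, columns=["trait", "environment", "chrom", "cm",
                                           "marker", "lod", "additive", "pve"])


@dataclass(frozen=True)
class PermutationThreshold:
    trait: str
    n_permutations: int
    alpha: float
    lod_threshold: float


def _check_pheno(y: np.ndarray):
    y = np.asarray(y, dtype=float)
    if np.all(np.isnan(y)):
        raise ValueError("phenotype is entirely missing")
    return y


def interval_scan(grid: ScanGrid, y: np.ndarray, trait: str = "trait",
                  environment: str | None = None,
                  covariates: np.ndarray | None = None) -> ScanResult:
    """Haley-Knott interval scan of line values ``y`` (aligned with
    ``grid.lines``; NaN lines are dropped)."""
    y = _check_pheno(np.asarray(y, dtype=float))
    keep = ~np.isnan(y)
    lod, beta, r2 = scan_core(grid.scores[keep], y[keep],
                              None if covariates is None else covariates[keep])
    tbl = grid.positions.copy()
    tbl["lod"], tbl["additive"], tbl["r2"] = lod, beta, r2
    return ScanResult(trait, environment, tbl)


def select_cofactors(grid: ScanGrid, y: np.ndarray, n_cofactors: int) -> list[int]:
    """Forward selection of marker-position columns minimising residual
    variance; returns grid column indices."""
    y = _check_pheno(np.asarray(y, dtype=float))
    keep = ~np.isnan(y)
    n = int(keep.sum())
    if n_cofactors >= n / 5:
        raise ValueError(f"{n_cofactors} cofactors with {n} lines risks overfitting "
                         "(limit: n_lines / 5)")
    cand = grid.marker_columns()
    selected: list[int] = []
    for _ in range(n_cofactors):
        C = grid.scores[keep][:, selected] if selected else None
        lod, _, _ = scan_core(grid.scores[keep][:, cand], y[keep], C)
        best = int(np.argmax(lod))
        if lod[best] <= 0:
            break
        selected.append(int(cand[best]))
        cand = cand[cand != cand[best]]
    return selected


def cim_scan(grid: ScanGrid, y: np.ndarray, n_cofactors: int = 5,
             cofactor_window_cm: float = 10.0, trait: str = "trait",
             environment: str | None = None,
             cofactors: list[int] | None = None) -> ScanResult:
    """Composite interval mapping: interval scan with cofactor markers as
    covariates, excluding cofactors within ``cofactor_window_cm`` of the test
    position (cofactors on other chromosomes are always kept)."""
    y = _check_pheno(np.asarray(y, dtype=float))
    keep = ~np.isnan(y)
    if cofactors is None:
        cofactors = select_cofactors(grid, y, n_cofactors)
    if not cofactors:
        res = interval_scan(grid, y, trait, environment)
        res.cofactors = []
        return res
    pos = grid.positions
    co_chrom = pos["chrom"].to_numpy()[cofactors]
    co_cm = pos["cm"].to_numpy()[cofactors]
    lods = np.empty(len(pos))
    betas = np.empty(len(pos))
    r2s = np.empty(len(pos))
    for p in range(len(pos)):
        use = ~((co_chrom == pos["chrom"].iloc[p]) &
                (np.abs(co_cm - pos["cm"].iloc[p]) <= cofactor_window_cm))
        C = grid.scores[keep][:, np.asarray(cofactors)[use]] if use.any() else None
        lod, beta, r2 = scan_core(grid.scores[keep][:, [p]], y[keep], C)
        lods[p], betas[p], r2s[p] = lod[0], beta[0], r2[0]
    tbl = pos.copy()
    tbl["lod"], tbl["additive"], tbl["r2"] = lods, betas, r2s
    return ScanResult(trait, environment, tbl, cofactors=list(cofactors))


def permutation_threshold(grid: ScanGrid, y: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          trait: str = "trait") -> PermutationThreshold:
    """Genome-wide LOD threshold: empirical (1 - alpha) quantile of the max
    LOD over ``n_perm`` scans with trait values permuted across lines."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = _check_pheno(np.asarray(y, dtype=float))
    keep = ~np.isnan(y)
    yk = y[keep]
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(yk) for _ in range(n_perm)])
    lod, _, _ = scan_core(grid.scores[keep], Y)
    max_lod = lod.max(axis=0)
    thr = float(np.quantile(max_lod, 1.0 - alpha, method="higher"))
    return PermutationThreshold(trait, n_perm, alpha, thr)


# ---------------------------------------------------------------------------
# multi-QTL summary

def multi_qtl_pve(grid: ScanGrid, peak_columns: list[int], y: np.ndarray) -> float:
    """Total phenotypic variance explained (%) by a joint linear model on all
    peak positions; collinear columns are dropped with a warning."""
    if not peak_columns:
        raise ValueError("need at least one peak")
    y = _check_pheno(np.asarray(y, dtype=float))
    keep = ~np.isnan(y)
    X = grid.scores[keep][:, peak_columns]
    yk = y[keep] - y[keep].mean()
    Xc = X - X.mean(axis=0)
    q, r, piv = _qr_pivot(Xc)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * max(1.0, abs(r[0, 0]))))
    if rank < Xc.shape[1]:
        warnings.warn(f"dropping {Xc.shape[1] - rank} collinear peak column(s)")
        Xc = Xc[:, piv[:rank]]
    beta, *_ = np.linalg.lstsq(Xc, yk, rcond=None)
    rss = float(np.sum((yk - Xc @ beta) ** 2))
    tss = float(np.sum(yk ** 2))
    return 100.0 * (1.0 - rss / tss)


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# epistasis

def epistasis_scan(genotype: np.ndarray, marker_pairs: list[tuple[int, int]],
                   y: np.ndarray, alpha: float = 0.001,
                   min_cell: int = 3) -> pd.DataFrame:
    """Two-locus interaction test per marker pair.

    For each pair the model y ~ x1 + x2 + x1:x2 is compared to the additive
    model by an F-test on the interaction term.  Lines undetermined at either
    marker are dropped; pairs with any two-locus genotype class below
    ``min_cell`` lines are skipped.
    """
    y = _check_pheno(np.asarray(y, dtype=float))
    rows = []
    for i, j in marker_pairs:
        if i == j:
            raise ValueError("a locus cannot be paired with itself")
        gi, gj = genotype[:, i], genotype[:, j]
        ok = np.isin(gi, (A, B)) & np.isin(gj, (A, B)) & ~np.isnan(y)
        cells = [(ga, gb) for ga in (A, B) for gb in (A, B)]
        counts = {c: int(np.sum((gi[ok] == c[0]) & (gj[ok] == c[1]))) for c in cells}
        if min(counts.values()) < min_cell:
            rows.append({"i": i, "j": j, "n": int(ok.sum()), "f_stat": np.nan,
                         "p_value": np.nan, "significant": False, "skipped": True})
            continue
        x1 = np.where(gi[ok] == B, 1.0, -1.0)
        x2 = np.where(gj[ok] == B, 1.0, -1.0)
        yk = y[ok]
        n = len(yk)
        X_add = np.column_stack([np.ones(n), x1, x2])
        X_full = np.column_stack([X_add, x1 * x2])
        rss_add = _ols_rss(X_add, yk)
        rss_full = _ols_rss(X_full, yk)
        df2 = n - X_full.shape[1]
        f = max(rss_add - rss_full, 0.0) / (rss_full / df2)
        p = float(stats.f.sf(f, 1, df2))
        rows.append({"i": i, "j": j, "n": n, "f_stat": f, "p_value": p,
                     "significant": p <= alpha, "skipped": False})
    return pd.DataFrame(rows, columns=["i", "j", "n", "f_stat", "p_value",
                                       "significant", "skipped"])


def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


# ---------------------------------------------------------------------------
# QTL naming

def name_qtl(peaks: pd.DataFrame, trait: str, merge_cm: float = 10.0) -> pd.DataFrame:
    """Merge peaks within ``merge_cm`` across environments and assign names
    q<Trait>_<chrom> (suffixed .1, .2 ... when one chromosome carries several
    distinct QTL)."""
    if peaks.empty:
        out = peaks.copy()
        out["qtl"] = pd.Series(dtype=str)
        return out
    out = peaks.sort_values(["chrom", "cm"]).reset_index(drop=True).copy()
    names = []
    for chrom in pd.unique(out["chrom"]):
        sub = out[out["chrom"] == chrom]
        cms = sub["cm"].to_numpy()
        cluster = np.zeros(len(cms), dtype=int)
        for k in range(1, len(cms)):
            cluster[k] = cluster[k - 1] + (1 if cms[k] - cms[k - 1] > merge_cm else 0)
        n_clusters = cluster.max() + 1
        for c in cluster:
            base = f"q{trait}_{chrom}"
            names.append(base if n_clusters == 1 else f"{base}.{c + 1}")
    out["qtl"] = names
    return out
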