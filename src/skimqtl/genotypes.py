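"""Sliding-window genotype calling, breakpoint detection and bin mapping.

The pipeline takes sparse, noisy parent-coded calls (A/B/missing) per RIL,
calls windows of consecutive observed SNPs homozygous for one parent when a
large-enough majority agrees, locates the A<->B transitions of the window
track, refines each transition to a flanking-call interval, and partitions
each chromosome into population-level recombination bins on a fixed bp grid.

Coordinates are bp (1-based SNP positions as in VCF) internally; BED output
is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import A, B, MISSING, UNDET, CODE_TO_CHAR


@dataclass
class ParentCodedGenotypes:
    """line x SNP call matrix in {A, B, missing}; SNPs sorted by (chrom, bp).

    Any call code outside {A, B} (heterozygous or missing) is treated as
    missing by every operation in this module.
    """

    lines: list[str]
    chroms: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.pos)):
            raise ValueError("calls shape mismatch")
        if len(self.chroms) != len(self.pos):
            raise ValueError("chroms/pos length mismatch")
        for c in self.chrom_names:
            p = self.pos[self.chroms == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def chrom_names(self) -> list[str]:
        seen, out = set(), []
        for c in self.chroms:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def snp_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)


def minor_allele_freq(calls: np.ndarray) -> np.ndarray:
    """Per-SNP MAF over non-missing A/B calls; NaN where no calls."""
    n_a = (calls == A).sum(axis=0).astype(float)
    n_b = (calls == B).sum(axis=0).astype(float)
    tot = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(n_a, n_b) / tot
    maf[tot == 0] = np.nan
    return maf


def filter_snps(g: ParentCodedGenotypes, maf_min: float = 0.2,
                line_missing_max: float = 1.0) -> ParentCodedGenotypes:
    """Drop SNPs with MAF < ``maf_min``, then lines with a missing-call
    fraction >= ``line_missing_max`` (SNP filter applied first, then the line
    filter on the retained SNPs).  MAF is computed over non-missing calls.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= line_missing_max <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    maf = minor_allele_freq(g.calls)
    keep_snps = np.nan_to_num(maf, nan=-1.0) >= maf_min
    if not keep_snps.any():
        raise ValueError("no SNPs left after MAF filter")
    calls = g.calls[:, keep_snps]
    observed = (calls == A) | (calls == B)
    miss_frac = 1.0 - observed.mean(axis=1)
    keep_lines = miss_frac < line_missing_max
    if not keep_lines.any():
        raise ValueError("no lines left after missingness filter")
    return ParentCodedGenotypes(
        lines=[l for l, k in zip(g.lines, keep_lines) if k],
        chroms=g.chroms[keep_snps],
        pos=g.pos[keep_snps],
        calls=calls[keep_lines],
    )


# ---------------------------------------------------------------------------
# window calling

@dataclass
class LineTrack:
    """Window calls for one line on one chromosome.

    Window ``w`` spans observed calls ``w .. w + window_size - 1`` (indices
    into ``obs_pos``/``obs_calls``, i.e. non-missing calls only).
    """

    obs_pos: np.ndarray       # bp of observed calls
    obs_calls: np.ndarray     # A/B
    win_call: np.ndarray      # per-window call A/B/UNDET
    window_size: int
    step: int = 1


@dataclass
class WindowCallTrack:
    tracks: dict               # (line, chrom) -> LineTrack
    lines: list[str]
    chrom_names: list[str]
    window_size: int
    homozygous_min: int


def _call_windows_1d(obs_calls: np.ndarray, window: int, hom_min: int, step: int) -> np.ndarray:
    n = len(obs_calls)
    if n < window:
        return np.empty(0, dtype=np.int8)
    is_b = (obs_calls == B).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(is_b)))
    starts = np.arange(0, n - window + 1, step)
    n_b = csum[starts + window] - csum[starts]
    n_a = window - n_b
    out = np.full(len(starts), UNDET, dtype=np.int8)
    out[n_a >= hom_min] = A
    out[n_b >= hom_min] = B
    return out


def call_windows(g: ParentCodedGenotypes, window_size: int = 18,
                 homozygous_min: int = 12, step: int = 1) -> WindowCallTrack:
    """Slide a window over each line's consecutive observed calls per
    chromosome; a window is called A (resp. B) when at least
    ``homozygous_min`` of its ``window_size`` observed calls are A (resp. B),
    else undetermined.  Lines with fewer than ``window_size`` observed calls
    on a chromosome get an empty (all-undetermined) track with a warning.
    """
    if homozygous_min > window_size:
        raise ValueError("homozygous_min must be <= window_size")
    if 2 * homozygous_min <= window_size:
        raise ValueError("homozygous_min must exceed window_size / 2")
    tracks = {}
    for chrom in g.chrom_names:
        idx = g.snp_indices(chrom)
        pos = g.pos[idx]
        for li, line in enumerate(g.lines):
            calls = g.calls[li, idx]
            obs = (calls == A) | (calls == B)
            obs_pos, obs_calls = pos[obs], calls[obs]
            if len(obs_calls) < window_size:
                warnings.warn(
                    f"line {line} chrom {chrom}: {len(obs_calls)} observed calls "
                    f"< window size {window_size}; whole chromosome undetermined")
            win = _call_windows_1d(obs_calls, window_size, homozygous_min, step)
            tracks[(line, chrom)] = LineTrack(obs_pos, obs_calls, win, window_size, step)
    return WindowCallTrack(tracks, list(g.lines), list(g.chrom_names),
                           window_size, homozygous_min)


# ---------------------------------------------------------------------------
# breakpoints

@dataclass
class BreakpointSet:
    """Per-line transition intervals plus the parental runs between them.

    ``breakpoints[(line, chrom)]`` is an ordered list of (left_bp, right_bp)
    intervals; ``runs[(line, chrom)]`` is the list of (genotype, start_bp,
    end_bp) parental segments delimited by those intervals (end-inclusive).
    """

    breakpoints: dict
    runs: dict
    lines: list[str]
    chrom_names: list[str]

    def per_chrom(self, chrom: str):
        return {line: self.breakpoints[(line, chrom)] for line in self.lines}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"line": line, "chrom": chrom, "left_bp": l, "right_bp": r}
            for (line, chrom), bps in self.breakpoints.items()
            for l, r in bps
        ]
        return pd.DataFrame(rows, columns=["line", "chrom", "left_bp", "right_bp"])


def _refine_transition(obs_calls, obs_pos, lo, hi, left_g, right_g):
    """Best split of obs indices [lo, hi] into a left_g block then a right_g
    block, minimising misassigned calls; returns the (left_bp, right_bp)
    interval spanned by the tied optimal splits."""
    seg = obs_calls[lo:hi + 1]
    is_right = (seg == right_g).astype(np.int64)
    is_left = (seg == left_g).astype(np.int64)
    # cost(s) for split after s-1 elements of seg, s in 0..len(seg)
    right_before = np.concatenate(([0], np.cumsum(is_right)))
    left_after = np.concatenate((np.cumsum(is_left[::-1])[::-1], [0]))
    cost = right_before + left_after
    # splits at the extremes would empty one run; keep s in 1..len-1
    cost = cost[1:-1]
    smin = int(np.argmin(cost))
    best = np.flatnonzero(cost == cost[smin]) + 1
    return int(obs_pos[lo + best.min() - 1]), int(obs_pos[lo + best.max()])


def detect_breakpoints(track: WindowCallTrack) -> BreakpointSet:
    """Emit one breakpoint per A<->B transition of each line's window track.

    Undetermined windows between two runs of the same genotype are absorbed
    (A -> U -> A yields no breakpoint).  Each transition is refined by
    re-segmenting the raw observed calls under the two windows flanking it,
    so that on complete noiseless data the interval is exactly (last call of
    the left parent block, first call of the right parent block).
    """
    w = track.window_size
    breakpoints, runs = {}, {}
    for key, t in track.tracks.items():
        bps, rns = [], []
        informative = np.flatnonzero(t.win_call != UNDET)
        if informative.size == 0:
            breakpoints[key], runs[key] = bps, rns
            continue
        # maximal runs of identical non-U window calls
        g_seq = t.win_call[informative]
        change = np.flatnonzero(np.diff(g_seq.astype(np.int16)) != 0)
        run_bounds = np.concatenate(([0], change + 1, [len(g_seq)]))
        run_info = []  # (genotype, first window idx, last window idx)
        for s, e in zip(run_bounds[:-1], run_bounds[1:]):
            run_info.append((int(g_seq[s]), int(informative[s]), int(informative[e - 1])))
        for (gl, _, wl), (gr, wr, _) in zip(run_info[:-1], run_info[1:]):
            lo = wl * t.step                       # first obs idx of last left window
            hi = wr * t.step + w - 1               # last obs idx of first right window
            bps.append(_refine_transition(t.obs_calls, t.obs_pos, lo, hi, gl, gr))
        # runs tile the chromosome between refined breakpoint intervals
        start = int(t.obs_pos[0])
        for i, (gi, _, _) in enumerate(run_info):
            end = bps[i][0] if i < len(bps) else int(t.obs_pos[-1])
            rns.append((gi, start, end))
            if i < len(bps):
                start = bps[i][1]
        breakpoints[key], runs[key] = bps, rns
    return BreakpointSet(breakpoints, runs, track.lines, track.chrom_names)


# ---------------------------------------------------------------------------
# bins

@dataclass
class BinMap:
    """Population-level recombination bins with one genotype per line per bin."""

    bins: pd.DataFrame          # chrom, start (0-based), end (half-open)
    genotype: np.ndarray        # (n_lines, n_bins) in {A, B, UNDET}
    lines: list[str]

    @property
    def bin_ids(self) -> list[str]:
        # 1-based start coordinate in the id, matching VCF-style coordinates
        return [f"bin_{c}_{int(s) + 1}" for c, s in zip(self.bins["chrom"], self.bins["start"])]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_bin_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())


def recombinant_intervals(bset: BreakpointSet, chrom: str, n_intervals: int,
                          interval_bp: int) -> np.ndarray:
    """Boolean grid: interval k is recombinant if any line's breakpoint
    interval overlaps [k*interval_bp, (k+1)*interval_bp)."""
    rec = np.zeros(n_intervals, dtype=bool)
    for line in bset.lines:
        for left, right in bset.breakpoints.get((line, chrom), []):
            k0 = max(0, (left - 1) // interval_bp)
            k1 = min(n_intervals - 1, (right - 1) // interval_bp)
            rec[k0:k1 + 1] = True
    return rec


def build_bins(bset: BreakpointSet, chrom_lengths: dict, interval_bp: int = 100_000) -> BinMap:
    """Merge runs of recombination-free grid intervals into bins.

    Each chromosome is cut into an ``interval_bp`` grid; an interval is
    recombinant when any line's breakpoint interval overlaps it.  A new bin
    starts at every recombinant interval; maximal runs of recombination-free
    intervals extend the current bin.  Because every breakpoint interval is
    contained in recombinant grid intervals, each bin consists of at most one
    leading recombinant (boundary) interval followed by recombination-free
    intervals; a line's bin genotype is read over the recombination-free part
    so that a line crossing over in the boundary region carries the left
    parent in the left bin and the right parent in the right bin.  The
    genotype is undetermined when the line's breakpoint falls inside the
    genotyped part (single-interval recombinant bins) or no window run covers
    it.
    """
    rows, geno_cols = [], []
    for chrom in bset.chrom_names:
        length = int(chrom_lengths[chrom])
        n_int = int(np.ceil(length / interval_bp))
        rec = recombinant_intervals(bset, chrom, n_int, interval_bp)
        starts = [0]
        for k in range(1, n_int):
            if rec[k]:
                starts.append(k * interval_bp)
        bounds = starts + [length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "start": s, "end": e})
            # genotype region: the bin minus its leading recombinant interval
            k0 = s // interval_bp
            gs = min(s + interval_bp, e - 1) if rec[k0] else s
            col = np.full(len(bset.lines), UNDET, dtype=np.int8)
            for li, line in enumerate(bset.lines):
                bps = bset.breakpoints.get((line, chrom), [])
                # bp interval inside the region (1-based inclusive vs 0-based half-open)
                if any(l < e + 1 and r > gs for l, r in bps):
                    continue
                hits = [g for g, rs, re_ in bset.runs.get((line, chrom), [])
                        if rs <= e and re_ > gs]
                if len(hits) == 1:
                    col[li] = hits[0]
            geno_cols.append(col)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genotype = (np.stack(geno_cols, axis=1) if geno_cols
                else np.empty((len(bset.lines), 0), dtype=np.int8))
    return BinMap(bins, genotype, list(bset.lines))


def bin_to_markers(binmap: BinMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One representative marker per bin.

    Returns (marker matrix with chrom/pos/per-line letter columns, BED frame
    of 0-based half-open bin boundaries).
    """
    ids = binmap.bin_ids
    cols = {
        "marker": ids,
        "chrom": binmap.bins["chrom"].to_numpy(),
        "pos": binmap.bins["start"].to_numpy() + 1,
    }
    lut = np.array([CODE_TO_CHAR[c] for c in range(4)])
    for li, line in enumerate(binmap.lines):
        cols[line] = lut[binmap.genotype[li]]
    mat = pd.DataFrame(cols)
    bed = pd.DataFrame({
        "chrom": binmap.bins["chrom"],
        "start": binmap.bins["start"],
        "end": binmap.bins["end"],
        "name": ids,
    })
    return mat, bed


def markers_to_binmap(mat: pd.DataFrame) -> BinMap:
    """Inverse of :func:`bin_to_markers` (end = next bin's start, or last pos)."""
    from .codes import CHAR_TO_CODE

    lines = [c for c in mat.columns if c not in ("marker", "chrom", "pos")]
    geno = np.stack([
        np.array([int(CHAR_TO_CODE[v]) for v in mat[line]], dtype=np.int8)
        for line in lines])
    starts = mat["pos"].to_numpy(dtype=np.int64) - 1
    chroms = mat["chrom"].astype(str).to_numpy()
    ends = np.empty_like(starts)
    for c in pd.unique(chroms):
        m = chroms == c
        s = starts[m]
        e = np.empty_like(s)
        e[:-1] = s[1:]
        e[-1] = s[-1] + 1
        ends[m] = e
    bins = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return BinMap(bins, geno, lines)
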