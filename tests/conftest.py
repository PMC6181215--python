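import numpy as np
import pandas as pd
import pytest

from skimqtl import popsim
from skimqtl.genotypes import ParentCodedGenotypes
from skimqtl.linkmap import build_linkage_map
from skimqtl.qtlscan import ScanGrid, scan_grid


@pytest.fixture(scope="session")
def small_map():
    return popsim.uniform_map(n_chrom=2, n_snps=600, length_bp=30_000_000, length_cm=80.0)


@pytest.fixture(scope="session")
def small_truth(small_map):
    return popsim.simulate_ril_genomes(small_map, popsim.PedigreeParams(60, 8), seed=42)


def clean_markers(truth, every: int = 20):
    """Marker frame + code matrix directly from true genotypes (no skim
    layer): every ``every``-th SNP becomes a marker; het codes stay HET and
    are treated as missing downstream."""
    idx = np.arange(0, truth.genotypes.shape[1], every)
    markers = pd.DataFrame({
        "marker": [f"m{k}" for k in range(len(idx))],
        "chrom": truth.chroms[idx],
        "pos": truth.pos[idx],
    })
    return markers, truth.genotypes[:, idx].copy()


def grid_from_truth(truth, every: int = 20, step_cm: float = 2.0) -> ScanGrid:
    markers, codes = clean_markers(truth, every)
    lm = build_linkage_map(markers, codes)
    return scan_grid(lm, codes, truth.lines, step_cm)


@pytest.fixture(scope="session")
def small_grid(small_truth):
    return grid_from_truth(small_truth, every=15, step_cm=2.0)


def toy_genotypes(calls, chrom="1", start=100, spacing=100):
    """ParentCodedGenotypes from a (lines x snps) int array on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    return ParentCodedGenotypes(
        lines=[f"L{i}" for i in range(n_lines)],
        chroms=np.repeat(chrom, n_snps),
        pos=start + spacing * np.arange(n_snps, dtype=np.int64),
        calls=calls,
    )
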