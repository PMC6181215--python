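import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skimqtl import popsim, qtlscan
from skimqtl.codes import A, B
from skimqtl.linkmap import build_linkage_map
from skimqtl.qtlscan import (cim_scan, epistasis_scan, interval_scan,
                             multi_qtl_pve, name_qtl, permutation_threshold,
                             scan_core, scan_grid, select_cofactors)

from conftest import clean_markers, grid_from_truth


def oracle_lod(x, y):
    """Independent single-marker regression LOD via the Pearson correlation:
    LOD = -(n/2) log10(1 - r^2)."""
    r, _ = stats.pearsonr(x, y)
    return -(len(y) / 2.0) * np.log10(1.0 - r * r)


@pytest.fixture(scope="module")
def planted():
    """188 lines, 3 chromosomes, one QTL at a known marker."""
    ms = popsim.uniform_map(3, 400, 20_000_000, 80.0)
    truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(188, 8), seed=21)
    grid = grid_from_truth(truth, every=10, step_cm=2.0)
    model = popsim.PhenotypeModel(
        [popsim.TraitSpec("T", qtl=(("2", 10_000_000, 0.7),), var_e=1.0)], 1, 1)
    ph = popsim.simulate_phenotypes(truth, model, 22)
    y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
    return truth, grid, y


class TestIntervalScan:
    def test_null_phenotype_flat(self, small_grid):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, len(small_grid.lines))
        res = interval_scan(small_grid, y)
        thr = permutation_threshold(small_grid, y, 200, 0.05, 1)
        assert res.max_lod < thr.lod_threshold

    def test_marker_lod_matches_regression_oracle(self, planted):
        truth, grid, y = planted
        res = interval_scan(grid, y)
        cols = grid.marker_columns()
        for c in cols[::7]:
            x = grid.scores[:, c]
            if np.std(x) < 1e-9:
                continue
            assert res.table["lod"].iloc[c] == pytest.approx(oracle_lod(x, y), abs=1e-8)

    def test_peak_near_planted_qtl(self, planted):
        truth, grid, y = planted
        res = interval_scan(grid, y)
        top = res.table.loc[res.table["lod"].idxmax()]
        qtl_cm = _true_cm(grid, truth, "2", 10_000_000)
        assert top["chrom"] == "2"
        assert abs(top["cm"] - qtl_cm) < 10.0

    def test_additive_effect_sign_and_size(self, planted):
        truth, grid, y = planted
        res = interval_scan(grid, y)
        top = res.table.loc[res.table["lod"].idxmax()]
        assert top["additive"] == pytest.approx(0.7, abs=0.25)

    def test_affine_invariance(self, planted):
        _, grid, y = planted
        res1 = interval_scan(grid, y)
        res2 = interval_scan(grid, 3.5 * y - 11.0)
        np.testing.assert_allclose(res1.table["lod"], res2.table["lod"], atol=1e-8)

    def test_all_missing_raises(self, small_grid):
        with pytest.raises(ValueError):
            interval_scan(small_grid, np.full(len(small_grid.lines), np.nan))


def _true_cm(grid, truth, chrom, bp):
    """cM of the planted locus on the estimated map: nearest marker's cm."""
    tbl = grid.linkage_map.table
    sub = tbl[tbl["chrom"] == chrom]
    k = (sub["bp"] - bp).abs().idxmin()
    return float(sub.loc[k, "cm"])


class TestScanCore:
    def test_matrix_and_vector_agree(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 4))
        lod_m, beta_m, _ = scan_core(X, Y)
        for j in range(4):
            lod_v, beta_v, _ = scan_core(X, Y[:, j])
            np.testing.assert_allclose(lod_m[:, j], lod_v, atol=1e-12)
            np.testing.assert_allclose(beta_m[:, j], beta_v, atol=1e-12)

    def test_monomorphic_column_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        lod, beta, r2 = scan_core(X, rng.normal(size=30))
        assert lod[0] == 0.0 and beta[0] == 0.0 and r2[0] == 0.0


class TestCim:
    def test_zero_cofactors_reduces_to_interval(self, planted):
        _, grid, y = planted
        a = interval_scan(grid, y)
        b = cim_scan(grid, y, n_cofactors=0)
        np.testing.assert_allclose(a.table["lod"], b.table["lod"], atol=1e-12)

    def test_overfit_guard(self, small_grid):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(small_grid.lines))
        with pytest.raises(ValueError, match="overfit"):
            select_cofactors(small_grid, y, n_cofactors=len(small_grid.lines) // 5 + 1)

    def test_cofactor_excluded_at_test_position(self, planted):
        _, grid, y = planted
        cof = select_cofactors(grid, y, 2)
        res = cim_scan(grid, y, cofactors=cof)
        # at the cofactor's own position the scan must still produce a
        # finite LOD computed without that cofactor
        for c in cof:
            assert np.isfinite(res.table["lod"].iloc[c])
        assert res.cofactors == cof

    def test_separates_linked_qtl(self):
        # two QTL 40 cM apart on one chromosome
        ms = popsim.uniform_map(1, 500, 20_000_000, 100.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(500, 8), seed=31)
        grid = grid_from_truth(truth, every=10, step_cm=1.0)
        q1_bp, q2_bp = 6_000_000, 14_000_000   # 30 and 70 cM
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("T", qtl=(("1", q1_bp, 0.6), ("1", q2_bp, 0.6)),
                              var_e=1.0)], 1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 32)
        y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
        res = cim_scan(grid, y, n_cofactors=4, cofactor_window_cm=15.0)
        thr = permutation_threshold(grid, y, 200, 0.05, 2)
        res.threshold = thr.lod_threshold
        peaks = res.peaks()
        cms = sorted(peaks["cm"])
        t1, t2 = _true_cm(grid, truth, "1", q1_bp), _true_cm(grid, truth, "1", q2_bp)
        assert any(abs(c - t1) < 10 for c in cms)
        assert any(abs(c - t2) < 10 for c in cms)


class TestPermutationThreshold:
    def test_fixed_seed_reproducible(self, small_grid):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(small_grid.lines))
        t1 = permutation_threshold(small_grid, y, 200, 0.05, 42)
        t2 = permutation_threshold(small_grid, y, 200, 0.05, 42)
        assert t1.lod_threshold == t2.lod_threshold

    def test_alpha_one_gives_minimum(self, small_grid):
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(small_grid.lines))
        thr = permutation_threshold(small_grid, y, 100, 1.0, 3)
        hi = permutation_threshold(small_grid, y, 100, 0.05, 3)
        assert thr.lod_threshold <= hi.lod_threshold

    def test_minimum_permutations(self, small_grid):
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(small_grid.lines))
        with pytest.raises(ValueError):
            permutation_threshold(small_grid, y, 50, 0.05, 1)


class TestMultiQtlPve:
    def test_single_peak_equals_marginal_r2(self, planted):
        _, grid, y = planted
        res = interval_scan(grid, y)
        top = int(res.table["lod"].idxmax())
        pve = multi_qtl_pve(grid, [top], y)
        assert pve == pytest.approx(100.0 * res.table["r2"].iloc[top], abs=1e-8)

    def test_joint_pve_bounded_by_marginals(self):
        ms = popsim.uniform_map(2, 200, 20_000_000, 80.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(300, 8), seed=41)
        grid = grid_from_truth(truth, every=10, step_cm=2.0)
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("T", qtl=(("1", 10_000_000, 0.5), ("2", 10_000_000, 0.5)),
                              var_e=1.0)], 1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 42)
        y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
        res = interval_scan(grid, y)
        tops = [int(res.table[res.table["chrom"] == c]["lod"].idxmax()) for c in ("1", "2")]
        joint = multi_qtl_pve(grid, tops, y)
        marg = sum(100.0 * res.table["r2"].iloc[t] for t in tops)
        assert joint <= marg + 1.0

    def test_variance_share_recovery(self):
        # one QTL explaining ~50% of variance at n=1000
        ms = popsim.uniform_map(1, 100, 20_000_000, 60.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(1000, 8), seed=43)
        grid = grid_from_truth(truth, every=5, step_cm=2.0)
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("T", qtl=(("1", 10_000_000, 1.0),), var_e=1.0)], 1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 44)
        y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
        res = interval_scan(grid, y)
        top = int(res.table["lod"].idxmax())
        pve = multi_qtl_pve(grid, [top], y)
        assert pve == pytest.approx(50.0, abs=5.0)

    def test_collinear_dropped(self, planted):
        _, grid, y = planted
        top = int(interval_scan(grid, y).table["lod"].idxmax())
        with pytest.warns(UserWarning, match="collinear"):
            pve2 = multi_qtl_pve(grid, [top, top], y)
        assert pve2 == pytest.approx(multi_qtl_pve(grid, [top], y), abs=1e-8)


class TestEpistasis:
    def test_self_pair_rejected(self, planted):
        truth, _, y = planted
        with pytest.raises(ValueError):
            epistasis_scan(truth.genotypes, [(5, 5)], y)

    def test_additive_simulation_calibrated(self):
        ms = popsim.uniform_map(2, 60, 20_000_000, 80.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(200, 8), seed=51)
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("T", qtl=(("1", 5_000_000, 0.5),), var_e=1.0)], 1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 52)
        y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
        rng = np.random.default_rng(53)
        pairs = [tuple(sorted(rng.choice(120, 2, replace=False))) for _ in range(300)]
        pairs = [p for p in set(pairs) if p[0] != p[1]]
        res = epistasis_scan(truth.genotypes, pairs, y, alpha=0.05)
        tested = res[~res["skipped"]]
        rate = tested["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / len(tested))
        assert rate < 0.05 + 4 * se

    def test_planted_interaction_detected(self):
        ms = popsim.uniform_map(2, 40, 20_000_000, 80.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(500, 8), seed=54)
        i = truth.locus_index("1", 10_000_000)
        j = truth.locus_index("2", 10_000_000)
        x1 = np.where(truth.genotypes[:, i] == B, 1.0, -1.0)
        x2 = np.where(truth.genotypes[:, j] == B, 1.0, -1.0)
        rng = np.random.default_rng(55)
        hits = 0
        for rep in range(10):
            y = 1.0 * x1 * x2 + rng.normal(0, 1, len(x1))
            res = epistasis_scan(truth.genotypes, [(i, j)], y, alpha=0.001)
            hits += int(res["significant"].iloc[0])
        assert hits >= 8

    def test_sparse_cells_skipped(self):
        rng = np.random.default_rng(56)
        g = np.zeros((20, 2), dtype=np.int8)
        g[:2, 1] = B                      # only 2 lines in one cell
        y = rng.normal(size=20)
        res = epistasis_scan(g, [(0, 1)], y)
        assert bool(res["skipped"].iloc[0])


class TestNaming:
    def test_merges_within_10cm(self):
        peaks = pd.DataFrame({
            "trait": ["Pro"] * 3, "environment": ["E1", "E2", "E1"],
            "chrom": ["20", "20", "20"], "cm": [50.0, 55.0, 90.0],
            "marker": ["a", "b", "c"], "lod": [5, 6, 4],
            "additive": [1, 1, 1], "pve": [10, 11, 8],
        })
        named = name_qtl(peaks, "Pro")
        assert list(named["qtl"]) == ["qPro_20.1", "qPro_20.1", "qPro_20.2"]

    def test_single_cluster_plain_name(self):
        peaks = pd.DataFrame({
            "trait": ["Oil"], "environment": ["E1"], "chrom": ["8"],
            "cm": [10.0], "marker": ["m"], "lod": [5.0],
            "additive": [-0.2], "pve": [6.0],
        })
        assert list(name_qtl(peaks, "Oil")["qtl"]) == ["qOil_8"]

    def test_empty_peaks(self):
        named = name_qtl(pd.DataFrame(columns=["trait", "environment", "chrom",
                                               "cm", "marker", "lod", "additive",
                                               "pve"]), "Suc")
        assert named.empty


class TestPleiotropy:
    def test_opposite_sign_coincident_peaks(self):
        ms = popsim.uniform_map(2, 300, 20_000_000, 80.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(188, 8), seed=61)
        grid = grid_from_truth(truth, every=10, step_cm=2.0)
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("Pro", qtl=(("2", 10_000_000, 0.8),), var_e=1.0),
             popsim.TraitSpec("Oil", qtl=(("2", 10_000_000, -0.5),), var_e=1.0)],
            1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 62)
        tops = {}
        for t in ("Pro", "Oil"):
            y = (ph[ph.trait == t].groupby("line")["value"].mean()
                 .reindex(truth.lines).to_numpy())
            res = interval_scan(grid, y, t)
            tops[t] = res.table.loc[res.table["lod"].idxmax()]
        assert tops["Pro"]["chrom"] == tops["Oil"]["chrom"] == "2"
        assert abs(tops["Pro"]["cm"] - tops["Oil"]["cm"]) < 10.0
        assert tops["Pro"]["additive"] > 0 > tops["Oil"]["additive"]


class TestBinVsDenseConcordance:
    def test_same_locus_found(self):
        # scan on bin markers and on a dense per-SNP map localise the same QTL
        ms = popsim.uniform_map(1, 600, 20_000_000, 80.0)
        truth = popsim.simulate_ril_genomes(ms, popsim.PedigreeParams(150, 8), seed=71)
        model = popsim.PhenotypeModel(
            [popsim.TraitSpec("T", qtl=(("1", 10_000_000, 1.0),), var_e=0.5)], 1, 1)
        ph = popsim.simulate_phenotypes(truth, model, 72)
        y = ph.groupby("line")["value"].mean().reindex(truth.lines).to_numpy()
        coarse = grid_from_truth(truth, every=30, step_cm=2.0)
        dense = grid_from_truth(truth, every=2, step_cm=1.0)
        top_c = coarse.positions.iloc[int(interval_scan(coarse, y).table["lod"].idxmax())]
        top_d = dense.positions.iloc[int(interval_scan(dense, y).table["lod"].idxmax())]
        bp_c = _nearest_bp(coarse, top_c)
        bp_d = _nearest_bp(dense, top_d)
        assert abs(bp_c - bp_d) < 3_000_000


def _nearest_bp(grid, row):
    tbl = grid.linkage_map.table
    hit = tbl[(tbl["chrom"] == row["chrom"]) & (tbl["marker"] == row["marker"])]
    return int(hit["bp"].iloc[0])
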