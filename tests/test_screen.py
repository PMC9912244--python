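"""Count normalization, LFC, permutation gene test and the control benchmark."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cas13guide.screen import (
    ScreenMatrix,
    control_benchmark,
    gene_negative_selection,
    guide_lfc,
    normalize_counts,
    read_count_matrix,
    write_count_matrix,
)


def _matrix(counts: np.ndarray, annotations=None, genes=None) -> ScreenMatrix:
    n = counts.shape[0]
    guides = [f"g{i}" for i in range(n)]
    cols = ["t0_rep1", "t1_rep1", "t1_rep2"][: counts.shape[1]]
    df = pd.DataFrame(counts, index=guides, columns=cols, dtype=float)
    roles = {c: ("t0" if c.startswith("t0") else "t1") for c in cols}
    ann = pd.Series(annotations if annotations is not None else ["other"] * n, index=guides)
    gmap = pd.Series(genes if genes is not None else ["geneA"] * n, index=guides)
    return ScreenMatrix(counts=df, sample_roles=roles, control_annotation=ann, gene_map=gmap)


class TestNormalization:
    def test_identical_columns_unit_factors(self):
        m = _matrix(np.tile(np.arange(1, 11)[:, None], (1, 2)))
        _, factors = normalize_counts(m, "none")
        np.testing.assert_allclose(factors, 1.0)

    def test_doubled_column_factor_ratio(self):
        base = np.arange(1, 11, dtype=float)
        m = _matrix(np.column_stack([base, 2 * base]))
        _, factors = normalize_counts(m, "none")
        assert factors.iloc[1] / factors.iloc[0] == pytest.approx(2.0)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample by c scales its factor ratio (what LFC sees) by c."""
        rng = np.random.default_rng(0)
        counts = rng.integers(10, 1000, (50, 2)).astype(float)
        _, f1 = normalize_counts(_matrix(counts), "none")
        scaled = counts.copy()
        scaled[:, 1] *= 3.0
        _, f2 = normalize_counts(_matrix(scaled), "none")
        r1 = f1.iloc[1] / f1.iloc[0]
        r2 = f2.iloc[1] / f2.iloc[0]
        assert r2 / r1 == pytest.approx(3.0)

    def test_control_subset_isolation(self):
        """Factors from non-essential controls ignore every other guide."""
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 500, (40, 2)).astype(float)
        ann = ["non_essential_target"] * 10 + ["other"] * 30
        _, f1 = normalize_counts(_matrix(counts, ann), "non_essential")
        perturbed = counts.copy()
        perturbed[10:, :] = rng.integers(1, 5000, (30, 2))
        _, f2 = normalize_counts(_matrix(perturbed, ann), "non_essential")
        np.testing.assert_allclose(f1, f2)

    def test_empty_control_set_error(self):
        m = _matrix(np.ones((10, 2)))
        with pytest.raises(ValueError, match="non_targeting"):
            normalize_counts(m, "non_targeting")


class TestGuideLfc:
    def test_equal_means_zero(self):
        m = _matrix(np.full((5, 2), 100.0))
        lfc = guide_lfc(m.counts, m.sample_roles)
        np.testing.assert_allclose(lfc, 0.0)

    def test_fourfold_change(self):
        m = _matrix(np.column_stack([np.full(5, 1000.0), np.full(5, 4000.0)]))
        lfc = guide_lfc(m.counts, m.sample_roles)
        np.testing.assert_allclose(lfc, 2.0, atol=0.01)

    def test_zero_endpoint_finite(self):
        m = _matrix(np.column_stack([np.full(5, 100.0), np.zeros(5)]))
        lfc = guide_lfc(m.counts, m.sample_roles)
        assert np.all(np.isfinite(lfc)) and np.all(lfc < 0)


class TestGeneNegativeSelection:
    def _series(self, values, genes):
        idx = [f"g{i}" for i in range(len(values))]
        return pd.Series(values, index=idx), pd.Series(genes, index=idx)

    def test_extreme_gene_hits_minimum_p(self):
        rng = np.random.default_rng(0)
        lfc = rng.normal(0, 1, 500)
        lfc[:5] = -100  # one gene owns the 5 lowest LFCs
        genes = ["hit"] * 5 + [f"gene{i // 5}" for i in range(495)]
        lfcs, gmap = self._series(lfc, genes)
        res = gene_negative_selection(lfcs, gmap, n_perm=1000, seed=0)
        assert res.loc["hit", "p"] == pytest.approx(1.0 / 1001)
        assert res["p"].min() >= 1.0 / 1001

    def test_duplicated_gene_symmetry(self):
        rng = np.random.default_rng(1)
        lfc = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 1, 4)])
        genes = [f"gene{i // 4}" for i in range(100)] + ["dup"] * 4
        lfc[100:] = lfc[:4]
        genes[:4] = ["orig"] * 4
        lfcs, gmap = self._series(lfc, genes)
        res = gene_negative_selection(lfcs, gmap, n_perm=2000, seed=2)
        # tied LFC values share midranks: identical score, identical p
        assert res.loc["orig", "score"] == res.loc["dup", "score"]
        assert res.loc["orig", "p"] == res.loc["dup", "p"]

    def test_low_n_perm_rejected(self):
        lfcs, gmap = self._series(np.arange(10.0), ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            gene_negative_selection(lfcs, gmap, n_perm=50)

    def test_singleton_gene_rejected(self):
        lfcs, gmap = self._series(np.arange(5.0), ["a"] * 4 + ["b"])
        with pytest.raises(ValueError, match="fewer than"):
            gene_negative_selection(lfcs, gmap, n_perm=200)

    def test_null_p_values_uniform(self):
        """Exchangeable LFCs: KS test against uniform passes across seeds."""
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lfc = rng.normal(0, 1, 600)
            genes = [f"gene{i // 3}" for i in range(600)]
            idx = [f"g{i}" for i in range(600)]
            res = gene_negative_selection(pd.Series(lfc, index=idx),
                                          pd.Series(genes, index=idx),
                                          n_perm=1000, seed=seed + 1)
            if kstest(res["p"], "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= 18

    def test_null_p_values_valid(self):
        """P(p <= alpha) <= alpha + Monte-Carlo tolerance under the null."""
        rng = np.random.default_rng(42)
        ps = []
        for rep in range(10):
            lfc = rng.normal(0, 1, 600)
            genes = [f"gene{i // 3}" for i in range(600)]
            idx = [f"g{i}" for i in range(600)]
            res = gene_negative_selection(pd.Series(lfc, index=idx),
                                          pd.Series(genes, index=idx),
                                          n_perm=1000, seed=rep)
            ps.extend(res["p"])
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1):
            assert (ps <= alpha).mean() <= alpha + 0.02

    def test_fdr_monotone_in_score_order(self):
        rng = np.random.default_rng(3)
        lfc = rng.normal(0, 1, 300)
        lfc[:30] -= 2.0
        genes = [f"gene{i // 3}" for i in range(300)]
        idx = [f"g{i}" for i in range(300)]
        res = gene_negative_selection(pd.Series(lfc, index=idx),
                                      pd.Series(genes, index=idx),
                                      n_perm=500, seed=0)
        assert (res["fdr"] >= res["p"] - 1e-12).all()
        assert (res["fdr"] <= 1.0).all()


@pytest.fixture(scope="module")
def benchmark(default_sim):
    noness = set(default_sim.truth.loc[
        ~default_sim.truth.essential & default_sim.truth.targeting, "gene"])
    bench = control_benchmark(default_sim.screen, default_sim.essential_genes,
                              noness, fdr_grid=(0.0, 0.05, 0.1, 0.25),
                              n_perm=2000, seed=11)
    return bench.set_index(["control", "fdr_cutoff"])


class TestControlBenchmark:
    def test_truth_set_validation(self, default_sim):
        with pytest.raises(ValueError, match="overlap"):
            control_benchmark(default_sim.screen, {"gene0001"}, {"gene0001"})
        with pytest.raises(ValueError, match="non-empty"):
            control_benchmark(default_sim.screen, set(), {"gene0001"})

    def test_zero_cutoff_calls_nothing(self, benchmark):
        for control in ("none", "non_targeting", "non_essential"):
            assert benchmark.loc[(control, 0.0), "tpr"] == 0.0
            assert benchmark.loc[(control, 0.0), "fpr"] == 0.0

    def test_rates_monotone_in_cutoff(self, benchmark):
        for control in ("none", "non_targeting", "non_essential"):
            sub = benchmark.loc[control].sort_index()
            assert (np.diff(sub["tpr"]) >= 0).all()
            assert (np.diff(sub["fpr"]) >= 0).all()

    def test_non_targeting_controls_inflate_false_positives(self, benchmark):
        assert benchmark.loc[("non_targeting", 0.1), "fpr"] > \
            benchmark.loc[("non_essential", 0.1), "fpr"]

    def test_non_essential_controls_raise_sensitivity(self, benchmark):
        assert benchmark.loc[("non_essential", 0.1), "tpr"] > \
            benchmark.loc[("none", 0.1), "tpr"]


class TestCountMatrixIO:
    def test_roundtrip(self, default_sim, tmp_path):
        path = tmp_path / "counts.tsv"
        write_count_matrix(default_sim.screen, path)
        noness = set(default_sim.truth.loc[
            ~default_sim.truth.essential & default_sim.truth.targeting, "gene"])
        m = read_count_matrix(path, ["t0_rep1", "t0_rep2"], ["t1_rep1", "t1_rep2"],
                              nonessential_genes=noness)
        pd.testing.assert_frame_equal(m.counts, default_sim.screen.counts)
        pd.testing.assert_series_equal(m.control_annotation,
                                       default_sim.screen.control_annotation,
                                       check_names=False)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sgRNA\tfoo\ng1\t2\n")
        with pytest.raises(ValueError, match="Gene"):
            read_count_matrix(path, ["a"], ["b"])
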