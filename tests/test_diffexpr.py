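import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tadreg import diffexpr as de
from tadreg.io_formats import ExpressionStudy


def _study(values, diets, region="HT"):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({
        "region": [region] * len(samples), "diet": diets,
        "mouse": [f"m{i}" for i in range(len(samples))],
    }, index=samples)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionStudy(genes, samples, values, meta)


class TestFilterProbes:
    def test_probe_above_threshold_everywhere_kept(self):
        s = _study([[10, 10, 10, 10]], ["SC", "SC", "CM", "CM"])
        neg = {f"s{i}": 5.0 for i in range(4)}
        assert de.filter_probes(s, neg, min_arrays=4).genes == ["g0"]

    def test_probe_above_on_three_of_many_arrays_removed(self):
        values = np.full((1, 24), 5.0)
        values[0, :3] = 10.0
        s = _study(values, ["SC"] * 12 + ["CM"] * 12)
        neg = {f"s{i}": 5.0 for i in range(24)}
        assert de.filter_probes(s, neg, min_arrays=4).n_genes == 0

    def test_missing_negctrl_value_is_error(self):
        s = _study([[1.0, 2.0, 1.0, 2.0]], ["SC", "SC", "CM", "CM"])
        with pytest.raises(ValueError, match="s3"):
            de.filter_probes(s, {"s0": 1, "s1": 1, "s2": 1})

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(1, 12, (200, 8))
        s = _study(values, ["SC"] * 4 + ["CM"] * 4)
        neg = {f"s{i}": rng.uniform(4, 8) for i in range(8)}
        got = set(de.filter_probes(s, neg, factor=1.10, min_arrays=4).genes)
        expected = set()
        for i, g in enumerate(s.genes):
            n_above = sum(values[i, j] > 1.10 * neg[f"s{j}"] for j in range(8))
            if n_above >= 4:
                expected.add(g)
        assert got == expected


class TestCollapse:
    def test_single_probe_row_unchanged_and_mean_of_two(self):
        s = _study([[2.0, 2.0, 2.0, 2.0],
                    [2.0, 4.0, 2.0, 4.0],
                    [4.0, 8.0, 4.0, 8.0]], ["SC", "SC", "CM", "CM"])
        out = de.collapse_replicates(s, {"g0": "A", "g1": "B", "g2": "B"})
        assert out.genes == ["A", "B"]
        np.testing.assert_array_equal(out.to_frame().loc["A"], [2, 2, 2, 2])
        np.testing.assert_array_equal(out.to_frame().loc["B"], [3, 6, 3, 6])

    def test_unmapped_probe_dropped_not_error(self):
        s = _study([[1.0] * 4, [2.0] * 4], ["SC", "SC", "CM", "CM"])
        out = de.collapse_replicates(s, {"g0": "A"})
        assert out.genes == ["A"]

    def test_fifty_probe_fixture_matches_group_means(self):
        rng = np.random.default_rng(2)
        values = rng.normal(7, 1, (50, 6))
        s = _study(values, ["SC"] * 3 + ["CM"] * 3)
        mapping = {f"g{i}": f"gene{i % 12}" for i in range(50)}
        out = de.collapse_replicates(s, mapping)
        frame = out.to_frame()
        for gene in frame.index:
            rows = [i for i in range(50) if mapping[f"g{i}"] == gene]
            np.testing.assert_allclose(frame.loc[gene].values,
                                       values[rows].mean(axis=0), atol=1e-12)


class TestModeratedT:
    @pytest.fixture()
    def random_study(self):
        rng = np.random.default_rng(3)
        return _study(rng.normal(7, 1, (100, 8)), ["SC"] * 4 + ["CM"] * 4)

    def test_d0_zero_recovers_ordinary_t(self, random_study):
        res = de.fit_de(random_study, "HT", d0=0.0)
        x = random_study.values
        t_ref, p_ref = stats.ttest_ind(x[:, 4:].T, x[:, :4].T, equal_var=True)
        np.testing.assert_allclose(res.table["t"].values, t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["pvalue"].values, p_ref, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_everywhere(self, random_study):
        res = de.fit_de(random_study, "HT", d0=np.inf, s0_squared=2.0)
        assert (res.table["posterior_var"] == 2.0).all()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        s = _study(rng.normal(0, 1, (2000, 8)), ["SC"] * 4 + ["CM"] * 4)
        res = de.fit_de(s, "HT")
        ks = stats.kstest(res.table["pvalue"].values, "uniform").statistic
        assert ks < 0.05

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(5)
        s = _study(rng.normal(0, 1, (2000, 8)), ["SC"] * 4 + ["CM"] * 4)
        res = de.fit_de(s, "HT")
        frac = (res.table["pvalue"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_shrinkage_reduces_denominator_spread(self, random_study):
        res = de.fit_de(random_study, "HT")
        assert res.params.d0 > 0
        assert np.var(res.table["posterior_var"]) <= np.var(res.params.s2)

    def test_constant_gene_gets_t_zero_p_one(self):
        values = np.vstack([np.full(8, 5.0),
                            np.random.default_rng(0).normal(0, 1, 8)])
        s = _study(values, ["SC"] * 4 + ["CM"] * 4)
        res = de.fit_de(s, "HT", d0=0.0)
        assert res.table.at["g0", "t"] == 0.0
        assert res.table.at["g0", "pvalue"] == 1.0

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same two-group
        contrast reproduces the moderated t and the hyperparameters."""
        rng = np.random.default_rng(6)
        x = rng.normal(6, 1, (60, 8))
        x[:10, 4:] += 1.0
        pd.DataFrame(x).to_csv(tmp_path / "x.csv", index=False)
        script = tmp_path / "ref.R"
        script.write_text("""
suppressMessages(library(limma))
x <- as.matrix(read.csv(commandArgs(TRUE)[1]))
design <- cbind(1, c(rep(0, 4), rep(1, 4)))
fit <- eBayes(lmFit(x, design))
out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                  d0 = fit$df.prior, s0sq = fit$s2.prior)
write.csv(out, commandArgs(TRUE)[2], row.names = FALSE)
""")
        proc = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "x.csv"),
             str(tmp_path / "ref.csv")], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "ref.csv")
        s = _study(x, ["SC"] * 4 + ["CM"] * 4)
        res = de.fit_de(s, "HT")
        assert res.params.d0 == pytest.approx(ref["d0"][0], rel=1e-4)
        assert res.params.s0_squared == pytest.approx(ref["s0sq"][0], rel=1e-4)
        np.testing.assert_allclose(res.table["t"].values, ref["t"].values,
                                   rtol=1e-6)
        np.testing.assert_allclose(res.table["pvalue"].values, ref["p"].values,
                                   rtol=1e-6)


class TestBH:
    def test_single_p_identity(self):
        assert de.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(de.bh_adjust(p), ref, atol=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        adj = de.bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestSelectDE:
    def _result(self, log2fc, q):
        table = pd.DataFrame({
            "log2fc": log2fc, "t": 0.0, "pvalue": q, "adj_pvalue": q,
            "df_residual": 6.0, "posterior_var": 1.0,
        }, index=[f"g{i}" for i in range(len(log2fc))])
        return de.DEResult(region="HT", table=table)

    def test_fold_change_just_below_threshold_excluded(self):
        res = self._result([0.58], [0.001])     # FC ~ 1.49
        assert de.select_de(res, fc_min=1.5, q_max=0.05) == {}

    def test_hypothalamus_thresholds_include_signed_gene(self):
        res = self._result([1.1], [0.04])
        assert de.select_de(res, fc_min=1.5, q_max=0.05) == {"g0": 1}

    def test_degenerate_thresholds_return_all_nonzero(self):
        res = self._result([0.5, -0.2, 0.0], [0.99, 0.5, 0.01])
        sel = de.select_de(res, fc_min=1.0, q_max=1.0 + 1e-12)
        assert sel == {"g0": 1, "g1": -1}

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(9)
        fc = rng.normal(0, 1, 300)
        q = rng.uniform(size=300)
        res = self._result(fc, q)
        sel = de.select_de(res, fc_min=1.5, q_max=0.05)
        expected = {f"g{i}": int(np.sign(fc[i])) for i in range(300)
                    if abs(fc[i]) >= np.log2(1.5) and q[i] < 0.05}
        assert sel == expected


class TestMDS:
    @pytest.fixture()
    def four_samples(self):
        rng = np.random.default_rng(10)
        return _study(rng.normal(7, 1, (600, 4)), ["SC", "SC", "CM", "CM"])

    def test_distance_matrix_symmetric_zero_diagonal(self, four_samples):
        d = de.leading_logfc_distance(four_samples, top=500)
        np.testing.assert_allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_distances_match_brute_force_sort_and_rms(self, four_samples):
        top = 500
        d = de.leading_logfc_distance(four_samples, top=top)
        x = four_samples.values
        for i in range(4):
            for j in range(4):
                diffs = sorted(np.abs(x[:, i] - x[:, j]), reverse=True)[:top]
                assert d.values[i, j] == pytest.approx(
                    np.sqrt(np.mean(np.square(diffs))), abs=1e-12)

    def test_duplicated_sample_lands_on_identical_coordinates(self):
        rng = np.random.default_rng(11)
        x = rng.normal(7, 1, (100, 3))
        x = np.column_stack([x, x[:, 0]])
        s = _study(x, ["SC", "SC", "CM", "CM"])
        coords = de.mds_leading_logfc(s, top=50)
        np.testing.assert_allclose(coords.loc["s0"].values,
                                   coords.loc["s3"].values, atol=1e-8)
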