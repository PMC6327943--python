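from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from tadreg import pheno_correlation as pc
from tadreg.io_formats import ExpressionStudy, PhenotypeTable
from tadreg.synthetic_data import make_genome, make_study


def _region_study(values, mice, diets, region="FC"):
    values = np.asarray(values, dtype=float)
    samples = [f"{m}_{region}" for m in mice]
    meta = pd.DataFrame({"region": region, "diet": diets, "mouse": mice},
                        index=samples)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionStudy(genes, samples, values, meta)


class TestPcaComposite:
    def test_two_identical_variables_explain_everything(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 10)
        t = pd.DataFrame({"diet": ["SC"] * 5 + ["CM"] * 5, "a": v, "b": v},
                         index=[f"m{i}" for i in range(10)])
        comp = pc.pca_composite(PhenotypeTable(t), ["a", "b"])
        assert comp.explained_fraction == pytest.approx(1.0)
        r = np.corrcoef(comp.scores.values, v)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_uncorrelated_variables_split_variance(self):
        rng = np.random.default_rng(1)
        n = 1000
        t = pd.DataFrame({"diet": ["SC"] * (n // 2) + ["CM"] * (n // 2),
                          "a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)},
                         index=[f"m{i}" for i in range(n)])
        comp = pc.pca_composite(PhenotypeTable(t), ["a", "b"])
        assert comp.explained_fraction == pytest.approx(0.5, abs=0.05)

    def test_recovers_planted_latent_factor(self, small_config, small_genome):
        _, pheno, truth = make_study(small_genome, config=small_config)
        comp = pc.pca_composite(pheno, list(pc.COMPOSITES["compulsivity"]))
        r = np.corrcoef(comp.scores.values,
                        truth.latent_factors["compulsivity"].values)[0, 1]
        assert abs(r) > 0.9

    def test_constant_variable_is_error(self):
        t = pd.DataFrame({"diet": ["SC", "SC", "CM", "CM"],
                          "a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]},
                         index=list("wxyz"))
        with pytest.raises(ValueError, match="constant"):
            pc.pca_composite(PhenotypeTable(t), ["a", "b"])

    def test_missing_values_drop_the_mouse(self):
        t = pd.DataFrame({"diet": ["SC"] * 3 + ["CM"] * 3,
                          "a": [1, 2, np.nan, 4, 5, 6.0],
                          "b": [2, 1, 3, 5, 4, 6.0]},
                         index=[f"m{i}" for i in range(6)])
        comp = pc.pca_composite(PhenotypeTable(t), ["a", "b"])
        assert "m2" not in comp.scores.index and len(comp.scores) == 5

    def test_sign_convention_first_loading_nonnegative(self, toy_phenotypes):
        comp = pc.pca_composite(toy_phenotypes, ["final_weight", "pct_gain"])
        assert comp.loadings.iloc[0] >= 0
        assert np.linalg.norm(comp.loadings.values) == pytest.approx(1.0)


class TestSpearmanFisher:
    def test_monotone_gene_has_rho_plus_minus_one(self):
        mice = [f"m{i}" for i in range(6)]
        score = pd.Series(np.arange(6.0), index=mice)
        values = np.vstack([np.arange(6.0) * 0.3 + 5,        # increasing
                            -np.arange(6.0) * 0.3 + 5])      # decreasing
        s = _region_study(values, mice, ["SC"] * 3 + ["CM"] * 3)
        res = pc.spearman_fisher(s, score)
        assert res.table.at["g0", "rho"] == pytest.approx(1.0)
        assert res.table.at["g1", "rho"] == pytest.approx(-1.0)
        assert res.table.at["g0", "pvalue"] < 1e-100  # z-formula underflow floor

    def test_too_few_observations_is_error(self):
        mice = ["m0", "m1", "m2"]
        score = pd.Series([1.0, 2.0, 3.0], index=mice)
        s = _region_study(np.ones((1, 3)), mice, ["SC", "SC", "CM"])
        with pytest.raises(ValueError, match=">= 4"):
            pc.spearman_fisher(s, score)

    def test_zero_variance_gene_logged_as_null(self):
        mice = [f"m{i}" for i in range(6)]
        score = pd.Series(np.arange(6.0), index=mice)
        s = _region_study(np.ones((1, 6)), mice, ["SC"] * 3 + ["CM"] * 3)
        res = pc.spearman_fisher(s, score)
        assert res.table.at["g0", "rho"] == 0.0
        assert res.table.at["g0", "pvalue"] == 1.0

    def test_rho_matches_scipy(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        mice = [f"m{i}" for i in range(8)]
        score = pd.Series(rng.normal(0, 1, 8), index=mice)
        values = rng.normal(7, 1, (40, 8))
        s = _region_study(values, mice, ["SC"] * 4 + ["CM"] * 4)
        res = pc.spearman_fisher(s, score)
        for i in range(40):
            ref = spearmanr(values[i], score.values).statistic
            assert res.table["rho"].iloc[i] == pytest.approx(ref, abs=1e-12)

    def test_fisher_z_p_within_factor_two_of_exact_permutation_p(self):
        """At n = 8 the Fisher-z p is an approximation; the exact p over all
        8! rank permutations bounds its error to a factor of two."""
        rng = np.random.default_rng(3)
        mice = [f"m{i}" for i in range(8)]
        y = rng.normal(0, 1, 8)
        x = y + rng.normal(0, 1.2, 8)         # moderate correlation
        s = _region_study(x[np.newaxis, :], mice, ["SC"] * 4 + ["CM"] * 4)
        res = pc.spearman_fisher(s, pd.Series(y, index=mice))
        rho_obs = abs(res.table["rho"].iloc[0])
        p_z = res.table["pvalue"].iloc[0]

        ry = np.argsort(np.argsort(y)) + 1.0
        perms = np.array(list(permutations(np.argsort(np.argsort(x)) + 1.0)))
        pc_ = perms - perms.mean(axis=1, keepdims=True)
        yc = ry - ry.mean()
        rho_all = pc_ @ yc / np.sqrt((pc_ ** 2).sum(axis=1) * (yc ** 2).sum())
        p_exact = np.mean(np.abs(rho_all) >= rho_obs - 1e-12)
        assert p_exact / 2 <= p_z <= p_exact * 2


class TestSelectCorrelating:
    def _result(self, rho, q, change):
        t = pd.DataFrame({"rho": rho, "pvalue": q, "adj_pvalue": q,
                          "change": change},
                         index=[f"g{i}" for i in range(len(rho))])
        return pc.CorrelationResult(region="FC", variable="v", table=t)

    def test_small_change_excluded_despite_significance(self):
        res = self._result([0.95], [0.01], [0.08])
        assert pc.select_correlating(res) == {}

    def test_big_change_not_significant_excluded(self):
        res = self._result([0.8], [0.2], [0.25])
        assert pc.select_correlating(res) == {}

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(4)
        n = 200
        rho = rng.uniform(-1, 1, n)
        q = rng.uniform(size=n)
        change = rng.uniform(0, 0.3, n)
        res = self._result(rho, q, change)
        got = pc.select_correlating(res, min_change=1.10, q_max=0.05)
        expected = {f"g{i}": int(np.sign(rho[i])) for i in range(n)
                    if q[i] < 0.05 and change[i] >= 0.10 and rho[i] != 0}
        assert got == expected


class TestHighRhoProfile:
    def test_disjoint_universes_give_all_zero_histogram(self):
        corr = pc.CorrelationResult("FC", "v", pd.DataFrame(
            {"rho": [0.95]}, index=["gA"]))
        det = pd.DataFrame({"log2fc": [0.3]}, index=["gB"])
        out = pc.high_rho_fc_profile(corr, det)
        assert (out.values == 0).all()

    def test_fixture_matches_brute_force_binning(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(300)]
        rho = rng.uniform(-1, 1, 300)
        fc = rng.uniform(0, 1.5, 300)
        corr = pc.CorrelationResult("FC", "v", pd.DataFrame(
            {"rho": rho}, index=genes))
        det = pd.DataFrame({"log2fc": fc}, index=genes)
        bins = np.arange(0, 2.1, 0.1)
        out = pc.high_rho_fc_profile(corr, det, rho_min=0.9, fc_bins=bins)
        for k, (a, b) in enumerate(zip(bins[:-1], bins[1:])):
            for sign, col in ((1, "positive"), (-1, "negative")):
                expected = sum(
                    1 for i in range(300)
                    if abs(rho[i]) > 0.9 and np.sign(rho[i]) == sign
                    and a <= fc[i] < b)
                assert out[col].iloc[k] == expected

    def test_planted_subtle_effects_fill_the_low_fc_bins(self):
        """Correlating effects planted at |log2FC| 0.2-0.4 dominate the
        high-|rho| histogram's modal bin (full-scale study)."""
        from tadreg.diffexpr import fit_de
        from tadreg.synthetic_data import SimulationConfig
        cfg = SimulationConfig(seed=33, de_fraction=0.0)
        study, pheno, truth = make_study(make_genome(cfg), config=cfg)
        counts = None
        for region in ("FC", "ST", "HT"):     # aggregate regions x variables
            sub = study.subset_region(region)
            det = fit_de(study, region).table
            for variable in truth.phenotype_scores.columns:
                res = pc.spearman_fisher(sub, truth.phenotype_scores[variable],
                                         variable=variable)
                h = pc.high_rho_fc_profile(res, det).sum(axis=1)
                counts = h if counts is None else counts + h
        modal = counts.idxmax()
        assert modal in ("[0.2,0.3)", "[0.3,0.4)")


def test_null_fdr_control(small_genome, small_config):
    """Without planted correlating genes, few genes that pass the change
    gate also pass the FDR gate."""
    import dataclasses
    cfg = dataclasses.replace(small_config, seed=21, n_regulated_tads=0,
                              n_scattered_responsive=0)
    study, pheno, _ = make_study(make_genome(cfg), config=cfg)
    sub = study.subset_region("FC")
    scores = pc.phenotype_scores(pheno)
    res = pc.spearman_fisher(sub, scores["compulsivity"], "compulsivity")
    t = res.table
    n_change = int((t["change"] >= 0.10).sum())
    n_both = len(pc.select_correlating(res))
    assert n_both <= max(1, 0.05 * n_change)
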