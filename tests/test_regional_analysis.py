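"""Statistical kernels (Mann-Whitney, Pearson, OLS, VIF) and the pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import leptidiv as L
from leptidiv.regional_analysis import mann_whitney_u


def mw_enumeration_oracle(x, y):
    """Exhaustive two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    m = n1 * len(y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo = min(u_obs, m - u_obs)
    return min(1.0, np.mean(us <= lo + 1e-9) + np.mean(us >= m - lo - 1e-9))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p, method = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)
        assert method == "exact_enumeration"

    def test_identical_groups_p_one(self):
        _, p, _ = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, 2)
        x = rng.integers(0, 6, n1).astype(float)  # integer draws force ties
        y = rng.integers(0, 6, n2).astype(float)
        _, p, method = mann_whitney_u(x, y)
        assert method == "exact_enumeration"
        assert p == pytest.approx(mw_enumeration_oracle(x, y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.5, 1, 6)
        _, p, _ = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        u, p, method = mann_whitney_u(x, y)
        assert method == "normal_approximation"
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue)


class TestPearson:
    def test_perfect_linear(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [3.0, 5, 7, 9]})
        r, p, n = L.pearson_corr(df, "x", "y")
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_hand_arithmetic_oracle(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 3, 4]})
        r, _, _ = L.pearson_corr(df, "x", "y")
        x, y = df["x"], df["y"]
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_pairwise_deletion_and_zero_variance(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, 4], "y": [2.0, 1, 3, 4]})
        _, _, n = L.pearson_corr(df, "x", "y")
        assert n == 3
        const = pd.DataFrame({"x": [1.0, 1, 1], "y": [2.0, 1, 3]})
        r, p, _ = L.pearson_corr(const, "x", "y")
        assert np.isnan(r) and np.isnan(p)

    def test_null_distribution(self):
        rng = np.random.default_rng(3)
        rs = []
        ps = []
        for _ in range(100):
            df = pd.DataFrame(
                {"x": rng.normal(size=1000), "y": rng.normal(size=1000)}
            )
            r, p, _ = L.pearson_corr(df, "x", "y")
            rs.append(abs(r))
            ps.append(p)
        assert np.mean(np.array(rs) < 0.1) > 0.95
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


class TestMLR:
    def _exact_df(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "gc": rng.normal(size=n),
                "rho": rng.normal(size=n),
                "gene_density": rng.normal(size=n),
                "ds": rng.normal(size=n),
            }
        )
        df["pi_4d"] = (
            0.5 + 2.0 * df["gc"] - 1.5 * df["rho"] + 0.7 * df["gene_density"]
            + 3.0 * df["ds"]
        )
        return df

    def test_exact_fit_recovers_coefficients(self):
        res = L.fit_mlr(self._exact_df())[0]
        t = res.terms.set_index("term")["estimate"]
        assert t["intercept"] == pytest.approx(0.5, abs=1e-10)
        assert t["gc"] == pytest.approx(2.0, abs=1e-10)
        assert t["rho"] == pytest.approx(-1.5, abs=1e-10)
        assert t["gene_density"] == pytest.approx(0.7, abs=1e-10)
        assert t["ds"] == pytest.approx(3.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_normal_equations_satisfied(self):
        df = self._exact_df()
        df["pi_4d"] += np.random.default_rng(1).normal(0, 0.3, len(df))
        res = L.fit_mlr(df)[0]
        X = np.column_stack(
            [np.ones(len(df))]
            + [df[c].to_numpy() for c in ("gc", "rho", "gene_density", "ds")]
        )
        beta = res.terms["estimate"].to_numpy()
        grad = X.T @ (df["pi_4d"].to_numpy() - X @ beta)
        assert np.linalg.norm(grad) / np.linalg.norm(X.T @ df["pi_4d"].to_numpy()) < 1e-8

    def test_interaction_variants_reported_side_by_side(self):
        df = self._exact_df(120, seed=2)
        df["pi_4d"] += np.random.default_rng(2).normal(0, 0.2, len(df))
        results = L.fit_mlr(df, variant="with_interactions")
        tags = [r.variant for r in results]
        assert tags[0] == "main_effects"
        assert len(results) == 1 + 6  # all pairwise interactions of 4 predictors
        for r in results[1:]:
            assert ":" in r.terms["term"].iloc[-1]

    def test_rank_deficient_design_names_columns(self):
        df = self._exact_df(40, seed=3)
        df["ds"] = 2.0 * df["gc"]  # exact collinearity
        with pytest.raises(ValueError, match="gc~ds"):
            L.fit_mlr(df)


class TestVIF:
    def test_orthogonal_predictors_vif_one(self):
        n = 4000
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        vif = L.compute_vif(df, ["a", "b", "c"])
        assert (vif < 1.01).all() and (vif >= 1.0 - 1e-9).all()

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        vif = L.compute_vif(df, ["a", "b"])
        assert np.isinf(vif).all()

    def test_bivariate_closed_form(self):
        # correlation 0.8 -> VIF -> 1 / (1 - 0.64) ~ 2.78
        rng = np.random.default_rng(6)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        vif = L.compute_vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert vif["a"] == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_monotone_in_pairwise_correlation(self):
        rng = np.random.default_rng(7)
        n = 50_000
        a = rng.normal(size=n)
        noise = rng.normal(size=n)
        vifs = []
        for r in (0.2, 0.5, 0.8):
            b = r * a + np.sqrt(1 - r * r) * noise
            vifs.append(
                L.compute_vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])["a"]
            )
        assert vifs[0] < vifs[1] < vifs[2]


class TestPipeline:
    def test_low_high_direction_on_coupled_simulation(self):
        """With selection efficiency coupled to local diversity, low-diversity
        windows carry higher pN/pS (sign check on pooled windows)."""
        from conftest import analyse

        diffs = []
        for seed in range(3):
            cfg = L.SimulationConfig(
                seed=150 + seed, n_scaffolds=4, scaffold_length=200_000,
                n_genes_per_scaffold=16, window_size=50_000,
                selection_efficiency_coupling=1.2,
                mutation_rate_multiplier_sd=0.4,
                missing_genotype_rate=0.0, low_depth_rate=0.0,
            )
            res = analyse(cfg)
            wdiv = L.window_diversity(res["pv"], res["scmap"], res["grid"])
            wdiv = L.zscore_classify(wdiv)
            wsel = L.window_selection_stats(
                res["pv"], res["subs"], res["scmap"], res["grid"]
            )
            wt = wdiv.merge(wsel, on=["population", "scaffold", "start", "end"])
            inc = wt[wt["included"]].dropna(subset=["pn_ps"])
            lo = inc.loc[inc["diversity_class"] == "low", "pn_ps"].mean()
            hi = inc.loc[inc["diversity_class"] == "high", "pn_ps"].mean()
            diffs.append(lo - hi)
        assert np.mean(diffs) > 0

    def test_missing_inputs_error(self, tmp_path):
        with pytest.raises(ValueError, match="missing pipeline inputs"):
            L.run_pipeline(L.PipelineConfig(), tmp_path)
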