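import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hetmap import hetstats


class TestTukeyOutliers:
    def test_hand_computed_fences(self):
        # type-7 quartiles of {1,2,3,4,100}: Q1=2, Q3=4, IQR=2, upper fence 7
        calls, fences = hetstats.tukey_outliers([1, 2, 3, 4, 100], k=1.5)
        assert fences["q1"] == pytest.approx(2.0)
        assert fences["q3"] == pytest.approx(4.0)
        assert fences["upper"] == pytest.approx(7.0)
        assert len(calls) == 1
        assert calls.iloc[0]["label"] == "female-biased"
        assert calls.iloc[0]["value"] == 100

    def test_symmetric_values_balanced_labels(self):
        v = [-100, -1, -0.5, 0, 0.5, 1, 100]
        calls, _ = hetstats.tukey_outliers(v, k=1.5)
        assert (calls["label"] == "male-biased").sum() == 1
        assert (calls["label"] == "female-biased").sum() == 1

    def test_constant_vector_no_outliers(self):
        calls, fences = hetstats.tukey_outliers([2.0] * 10, k=1.5)
        assert calls.empty and fences["iqr"] == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            hetstats.tukey_fences(np.array([1.0, 2.0, 3.0]))

    def test_quartiles_match_sortbased_oracle(self):
        # explicit type-7: sorted v, q = v[f] + (h - f) * (v[c] - v[f])
        rng = np.random.default_rng(0)
        for n in range(4, 13):
            for _ in range(50):
                v = np.sort(rng.normal(size=n))
                for p, key in ((0.25, "q1"), (0.75, "q3")):
                    h = (n - 1) * p
                    f, c = int(np.floor(h)), int(np.ceil(h))
                    oracle = v[f] + (h - f) * (v[c] - v[f])
                    fences = hetstats.tukey_fences(v)
                    assert abs(fences[key] - oracle) < 1e-12


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1, 30, dtype=float)
        assert hetstats.spearman(x, 2 * x).rho == pytest.approx(1.0)
        assert hetstats.spearman(x, -(x ** 3)).rho == pytest.approx(-1.0)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=40)
            y = rng.normal(size=40) + 0.3 * x
            oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert abs(hetstats.spearman(x, y).rho - oracle) < 1e-12


class TestZoib:
    def test_no_boundary_reduces_to_beta_regression(self):
        rng = np.random.default_rng(1)
        y, x = hetstats.simulate_zoib(800, -0.5, 0.6, 8.0, 0.0, 0.0, rng=rng)
        fit = hetstats.zoib_fit(y, x, standardize=False)
        assert fit.zoi == 0.0
        # independent oracle: statsmodels beta regression
        from statsmodels.othermod.betareg import BetaModel

        sm_fit = BetaModel(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
        assert fit.beta1 == pytest.approx(sm_fit.params[1], abs=1e-4)

    def test_boundary_mass_estimates(self):
        rng = np.random.default_rng(2)
        y, x = hetstats.simulate_zoib(4000, 0.0, 0.5, 6.0, 0.3, 0.4, rng=rng)
        fit = hetstats.zoib_fit(y, x)
        assert fit.zoi == pytest.approx(0.3, abs=0.03)
        assert fit.coi == pytest.approx(0.4, abs=0.04)
        assert fit.phi == pytest.approx(6.0, rel=0.25)

    def test_no_interior_values_is_error(self):
        y = np.array([0.0, 1.0] * 50)
        with pytest.raises(ValueError):
            hetstats.zoib_fit(y, np.arange(100))

    def test_loglik_local_optimality(self):
        rng = np.random.default_rng(3)
        y, x = hetstats.simulate_zoib(600, -1.0, 0.8, 10.0, 0.2, 0.5, rng=rng)
        fit = hetstats.zoib_fit(y, x, standardize=False)
        best = fit.loglik
        for _ in range(100):
            params = {
                "beta0": rng.normal(0, 2),
                "beta1": rng.normal(0, 2),
                "phi": rng.uniform(0.5, 40),
                "zoi": rng.uniform(0.01, 0.99),
                "coi": rng.uniform(0.01, 0.99),
            }
            assert hetstats.zoib_loglik(params, x, y) <= best + 1e-6


class TestAssociationSuite:
    def _table(self, rng, n=400, signal=False):
        dist_rel = rng.uniform(0, 0.5, n)
        gene_count = rng.poisson(8, n)
        rate_f = rng.gamma(4, 0.5, n)
        rate_m = rng.gamma(4, 0.5, n)
        if signal:
            rate_m = rate_m + 3.0 * np.exp(-10 * dist_rel)
        diff, hi, resc = (rate_f - rate_m, None, None)
        d, h, r = __import__("hetmap").landscape.interval_heterochiasmy(rate_f, rate_m)
        return pd.DataFrame(
            {
                "chrom": "1",
                "start_bp": np.arange(n) * 10 ** 6,
                "end_bp": (np.arange(n) + 1) * 10 ** 6,
                "n_snps": 10,
                "class": np.where(np.arange(n) % 2 == 0, "macro", "micro"),
                "rate_f": rate_f,
                "rate_m": rate_m,
                "rate_avg": (rate_f + rate_m) / 2,
                "diff": d,
                "hi": h,
                "hi_rescaled": r,
                "gene_count": gene_count,
                "dist_bp": dist_rel * 10 ** 7,
                "dist_rel": dist_rel,
            }
        )

    def test_null_landscape_shows_no_association(self):
        rng = np.random.default_rng(7)
        report = hetstats.association_suite(self._table(rng))
        sp = report["spearman"].set_index(["response", "covariate"])
        assert abs(sp.loc[("abs_diff", "gene_count"), "rho"]) < 0.12
        assert abs(sp.loc[("rate_avg", "gene_count"), "rho"]) < 0.12
        fit = report["zoib"]["dist_rel"]
        lo, hi = fit.ci_beta1
        assert lo < 0 < hi

    def test_end_biased_signal_detected(self):
        rng = np.random.default_rng(8)
        report = hetstats.association_suite(self._table(rng, signal=True))
        sp = report["spearman"].set_index(["response", "covariate"])
        assert sp.loc[("abs_diff", "dist_rel"), "rho"] < -0.2
        assert len(report["outliers"]["calls"]) >= len(report["extreme"]["calls"])
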