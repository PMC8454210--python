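"""Agreement metrics, trait dispersion, and the statistical benchmark."""

import numpy as np
import pandas as pd
import pytest

from leafopt import agreement_stats, benchmark_regression, cv_within_across
from leafopt.evaluation import site_means
from leafopt.exceptions import InsufficientDataError


class TestAgreementStats:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement_stats(obs, obs)
        assert s.r == pytest.approx(1.0) and s.rmse == 0.0
        assert s.r_squared_identity == pytest.approx(1.0)

    def test_constant_offset(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement_stats(obs, obs + 0.5)
        assert s.r == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.5)
        # bias shows in the 1:1-line R2 but not in squared correlation
        assert s.r_squared_identity < s.r_squared

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(21)
        obs = rng.normal(10.0, 2.0, 40)
        pred = obs + rng.normal(0.0, 1.0, 40)
        s = agreement_stats(obs, pred)
        # independent evaluation from the definitions
        r_ref = (np.mean((obs - obs.mean()) * (pred - pred.mean()))
                 / (obs.std() * pred.std()))
        rmse_ref = np.sqrt(np.mean((pred - obs) ** 2))
        assert s.r == pytest.approx(r_ref, rel=1e-10)
        assert s.rmse == pytest.approx(rmse_ref, rel=1e-12)
        assert s.relative_rmse == pytest.approx(rmse_ref / obs.mean(), rel=1e-12)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(22)
        obs = rng.normal(0.0, 1.0, 30)
        pred = rng.normal(0.0, 1.0, 30)
        s1 = agreement_stats(obs, pred)
        s2 = agreement_stats(obs, 5.0 * pred + 3.0)
        assert s1.r == pytest.approx(s2.r, rel=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        obs = rng.normal(5.0, 1.0, 25)
        pred = obs + rng.normal(0.0, 0.5, 25)
        perm = rng.permutation(25)
        s1, s2 = agreement_stats(obs, pred), agreement_stats(obs[perm], pred[perm])
        assert s1.r == pytest.approx(s2.r) and s1.rmse == pytest.approx(s2.rmse)

    def test_zero_variance_flagged_not_raised(self):
        s = agreement_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(s.r)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])


class TestCV:
    @staticmethod
    def _table(values_by_site):
        rows = [{"site_id": sid, "ma": v, "leaf_habit": "deciduous"}
                for sid, vals in values_by_site.items() for v in vals]
        return pd.DataFrame(rows)

    def test_constant_trait(self):
        within, across = cv_within_across(
            self._table({"a": [5.0, 5.0], "b": [5.0, 5.0]}), "ma")
        assert np.allclose(within, 0.0) and across == 0.0

    def test_two_point_closed_form(self):
        within, _ = cv_within_across(
            self._table({"a": [1.0, 3.0], "b": [2.0, 2.0]}), "ma")
        assert within["a"] == pytest.approx(np.sqrt(2.0) / 2.0, rel=1e-12)

    def test_single_species_site_skipped(self):
        within, _ = cv_within_across(
            self._table({"a": [1.0, 3.0], "b": [2.0]}), "ma")
        assert "b" not in within.index

    def test_within_exceeds_across_when_noise_dominates(self):
        """A transect with big within-site noise and flat site means must
        show within-site CV above across-site CV."""
        rng = np.random.default_rng(31)
        table = self._table({
            f"s{i}": list(50.0 * np.exp(rng.normal(0.0, 0.4, 12)))
            for i in range(8)})
        within, across = cv_within_across(table, "ma")
        assert within.median() > across


class TestBenchmark:
    @staticmethod
    def _sites(n=18, noise=0.0, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "patm": rng.uniform(60, 100, n),
            "tdj": rng.uniform(5, 22, n),
            "d0": rng.uniform(0.2, 1.5, n),
        })
        df["chi"] = (0.9 - 0.1 * df["d0"] + 0.002 * df["tdj"]
                     + noise * rng.standard_normal(n))
        return df

    def test_linear_data_noise_free_r2_one(self):
        out = benchmark_regression(self._sites(noise=0.0), "chi")
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_r2_falls_with_noise(self):
        clean = benchmark_regression(self._sites(noise=0.0), "chi")
        noisy = benchmark_regression(self._sites(noise=0.2, seed=2), "chi")
        assert noisy["r_squared"] < clean["r_squared"]

    def test_permuted_response_near_chance(self):
        """After permuting the response, R2 should sit near its chance level
        p/(n-1) rather than near the fitted value."""
        rng = np.random.default_rng(33)
        r2s = []
        for seed in range(20):
            df = self._sites(n=30, noise=0.05, seed=seed)
            df["chi"] = rng.permutation(df["chi"].to_numpy())
            r2s.append(benchmark_regression(df, "chi")["r_squared"])
        p, n = 3, 30
        assert np.mean(r2s) == pytest.approx(p / (n - 1), abs=0.08)

    def test_overdetermined_design_rejected(self):
        with pytest.raises(InsufficientDataError):
            benchmark_regression(self._sites(n=4), "chi")


class TestSiteMeans:
    def test_deciduous_only_by_default(self):
        table = pd.DataFrame({
            "site_id": ["a"] * 4,
            "ma": [10.0, 12.0, 100.0, 120.0],
            "leaf_habit": ["deciduous", "deciduous", "evergreen", "evergreen"],
        })
        assert site_means(table, "ma")["a"] == pytest.approx(11.0)
        assert site_means(table, "ma", include_evergreen=True)["a"] == \
            pytest.approx(60.5)
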