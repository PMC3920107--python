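"""Log-binning, slope estimation, MLE family fits, AIC model selection."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semwalk import (
    degree_distribution,
    fit_family,
    log_bin,
    model_select,
    slope_estimate,
)
from semwalk.netbuild import SemanticNetwork
from semwalk.statfit import BinnedDistribution, FitError


class TestLogBin:
    def test_identical_values_single_bin(self):
        binned = log_bin([5.0] * 40)
        assert (binned.densities > 0).sum() == 1
        widths = np.diff(binned.bin_edges)
        assert float((binned.densities * widths).sum()) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,bpd", [(1, 5), (2, 3), (3, 10)])
    def test_density_integrates_to_one(self, seed, bpd):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(1.0, 1.2, size=2000)
        binned = log_bin(x, bins_per_decade=bpd)
        mass = float((binned.densities * np.diff(binned.bin_edges)).sum())
        assert mass == pytest.approx(1.0, abs=1e-9)

    def test_power_law_sample_recovers_slope(self):
        # inverse-CDF draws from density ~ x**-2 on [1, inf)
        rng = np.random.default_rng(12)
        x = rng.uniform(size=10_000) ** -1.0
        slope, _, r2 = slope_estimate(log_bin(x, bins_per_decade=5))
        assert slope == pytest.approx(-2.0, abs=0.25)
        assert r2 > 0.95

    def test_nonpositive_value_names_index(self):
        with pytest.raises(FitError, match="index 2"):
            log_bin([1.0, 2.0, -3.0])


class TestSlopeEstimate:
    @staticmethod
    def exact_power_law_bins(exponent, n_bins=12):
        edges = 10 ** (0.2 * np.arange(n_bins + 1))
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = centers**exponent
        dens /= float((dens * np.diff(edges)).sum())
        return BinnedDistribution(edges, dens)

    def test_exact_power_law(self):
        binned = self.exact_power_law_bins(-1.5)
        slope, _, r2 = slope_estimate(binned)
        assert slope == pytest.approx(-1.5, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_density_slope_zero(self):
        binned = self.exact_power_law_bins(0.0)
        slope, _, _ = slope_estimate(binned)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_too_few_bins_rejected(self):
        edges = np.array([1.0, 2.0, 4.0])
        dens = np.array([1.0, 0.0])  # integrates to 1, one occupied bin
        with pytest.raises(FitError, match="3 occupied"):
            slope_estimate(BinnedDistribution(edges, dens))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0.5, 1.0, size=800)
        s1, _, _ = slope_estimate(log_bin(x))
        s2, _, _ = slope_estimate(log_bin(c * x))
        assert s2 == pytest.approx(s1, abs=0.15)


class TestDegreeDistribution:
    def test_triangle(self):
        dd = degree_distribution(SemanticNetwork(nx.complete_graph(3)))
        assert sorted(dd.degrees.tolist()) == [2, 2, 2]

    def test_mean_is_2e_over_n(self):
        g = nx.gnm_random_graph(200, 1300, seed=4)
        dd = degree_distribution(SemanticNetwork(g))
        assert dd.mean() == pytest.approx(2 * 1300 / 200)
        assert dd.degrees.sum() == 2 * 1300


class TestFitFamily:
    def test_exponential_closed_form_no_offset(self):
        fit = fit_family([1.0, 2.0, 3.0], "exponential", xmin_policy="none")
        assert fit.params["rate"] == pytest.approx(0.5)
        assert fit.params["shift"] == 0.0

    def test_exponential_anchored_shifts_to_minimum(self):
        fit = fit_family([1.0, 2.0, 3.0], "exponential")
        assert fit.params["shift"] == 1.0
        assert fit.params["rate"] == pytest.approx(1.0)

    def test_pareto_closed_form(self):
        # alpha = 1 + 4 / (6 ln 2), independent arithmetic
        fit = fit_family([1.0, 2.0, 4.0, 8.0], "pareto")
        assert fit.params["alpha"] == pytest.approx(1 + 4 / (6 * math.log(2)),
                                                    abs=1e-12)
        assert fit.params["xmin"] == 1.0

    def test_pareto_explicit_xmin(self):
        fit = fit_family([2.0, 4.0, 8.0], "pareto", xmin_policy="explicit",
                         xmin=2.0)
        assert fit.params["xmin"] == 2.0
        with pytest.raises(FitError):
            fit_family([2.0, 4.0], "pareto", xmin_policy="explicit", xmin=3.0)

    @pytest.mark.parametrize("policy", ["none", "min_observed"])
    def test_lognormal_parameter_recovery(self, policy):
        rng = np.random.default_rng(42)
        x = rng.lognormal(mean=1.0, sigma=0.5, size=5000)
        fit = fit_family(x, "lognormal", xmin_policy=policy)
        assert fit.params["mu"] == pytest.approx(1.0, abs=0.05)
        assert fit.params["sigma"] == pytest.approx(0.5, abs=0.05)

    def test_exponential_parameter_recovery(self):
        rng = np.random.default_rng(43)
        x = rng.exponential(scale=1.0, size=5000)
        fit = fit_family(x, "exponential")
        assert fit.params["rate"] == pytest.approx(1.0, abs=0.05)

    def test_pareto_parameter_recovery(self):
        rng = np.random.default_rng(44)
        # numpy's pareto(a) has survival (1+x)^-a, so 1+x is classic Pareto
        # with xmin 1 and density exponent a + 1
        x = 1 + rng.pareto(2.5, size=5000)
        fit = fit_family(x, "pareto", xmin_policy="explicit", xmin=1.0)
        assert fit.params["alpha"] == pytest.approx(3.5, abs=0.08)

    def test_pareto_mle_matches_grid_search(self):
        rng = np.random.default_rng(7)
        x = 1 + rng.pareto(1.8, size=20)
        fit = fit_family(x, "pareto", xmin_policy="explicit", xmin=1.0)
        grid = np.linspace(1.01, 6.0, 50_000)
        n = len(x)
        # log-likelihood of f(x) = (a-1) / x^a on [1, inf), evaluated directly
        ll = n * np.log(grid - 1) - grid * np.log(x).sum()
        assert fit.params["alpha"] == pytest.approx(grid[np.argmax(ll)],
                                                    abs=1e-3)

    def test_truncated_lognormal_never_below_closed_form(self):
        # left-truncation correction can only raise the likelihood
        rng = np.random.default_rng(3)
        x = 1.0 + rng.lognormal(1.5, 0.6, size=400)  # support visibly shifted
        anchored = fit_family(x, "lognormal")
        raw = fit_family(x, "lognormal", xmin_policy="none")
        assert anchored.log_likelihood >= raw.log_likelihood - 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError, match="lognormal sd"):
            fit_family([2.0] * 20, "lognormal")
        with pytest.raises(FitError):
            fit_family([2.0] * 20, "exponential")
        with pytest.raises(FitError):
            fit_family([2.0] * 20, "pareto")
        with pytest.raises(FitError):
            fit_family([1.0, -1.0, 2.0] * 4, "exponential")
        with pytest.raises(FitError, match="unknown family"):
            fit_family([1.0, 2.0] * 6, "weibull")

    def test_aicc_penalty(self):
        x = np.linspace(1, 5, 12)
        plain = fit_family(x, "lognormal", use_aicc=False)
        corrected = fit_family(x, "lognormal", use_aicc=True)
        assert corrected.aic == pytest.approx(
            plain.aic + 2 * 2 * 3 / (12 - 2 - 1)
        )


class TestModelSelect:
    @pytest.mark.parametrize(
        "sampler,expected",
        [
            (lambda rng: rng.exponential(1.0, 1000), "exponential"),
            (lambda rng: rng.lognormal(0.0, 1.0, 1000), "lognormal"),
        ],
    )
    def test_true_family_wins_across_seeds(self, sampler, expected):
        wins = sum(
            model_select(sampler(np.random.default_rng(seed)))[0].family
            == expected
            for seed in range(100)
        )
        assert wins >= 95

    def test_single_family_gets_weight_one(self):
        rng = np.random.default_rng(1)
        [fit] = model_select(rng.exponential(1.0, 100), families=["exponential"])
        assert fit.akaike_weight == pytest.approx(1.0)

    def test_weights_are_softmax_of_half_delta(self):
        rng = np.random.default_rng(2)
        fits = model_select(rng.lognormal(0.5, 0.8, 500))
        aics = np.array([f.aic for f in fits])
        w = np.exp(-(aics - aics.min()) / 2)
        w /= w.sum()
        assert np.allclose([f.akaike_weight for f in fits], w)
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0, abs=1e-9)
        assert [f.aic for f in fits] == sorted(f.aic for f in fits)

    def test_empty_family_set_rejected(self):
        with pytest.raises(FitError):
            model_select([1.0, 2.0, 3.0] * 5, families=[])
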