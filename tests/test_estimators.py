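import numpy as np
import pandas as pd
import pytest

from oracles import irls_binomial

from cheatnet.estimators import (
    bird_estimates,
    cheating_frequency,
    glm_trend,
    innovative_proportion,
    overall_cheating,
    partner_diversity,
    proportion_cheaters,
    site_estimates,
    trend_tests,
)
from cheatnet.fieldsynth import FieldNetwork


def toy_network(legit, illegit, traits=None):
    legit = np.asarray(legit, dtype=float)
    n_p, n_b = legit.shape
    if traits is None:
        traits = np.column_stack(
            [np.linspace(10, 30, n_p), np.linspace(5, 25, n_p)]
        )
    return FieldNetwork(
        site_id="toy",
        elevation=1000.0,
        legit_freq=legit,
        illegit_freq=np.asarray(illegit, dtype=float),
        sampling_hours=np.full(n_p, 100.0),
        plant_traits=pd.DataFrame(
            traits, columns=["corolla_length", "curvature"]
        ),
        bird_bill_length=np.full(n_b, 20.0),
    )


class TestSiteProportions:
    def test_no_cheating(self):
        net = toy_network(np.ones((3, 4)), np.zeros((3, 4)))
        assert proportion_cheaters(net) == 0.0
        assert overall_cheating(net) == 0.0

    def test_all_birds_cheat(self):
        net = toy_network(np.ones((3, 4)), np.ones((3, 4)))
        assert proportion_cheaters(net) == 1.0

    def test_three_of_ten_birds(self):
        legit = np.ones((2, 10))
        illegit = np.zeros((2, 10))
        illegit[0, :3] = 0.5
        net = toy_network(legit, illegit)
        assert proportion_cheaters(net) == pytest.approx(0.3)

    def test_overall_cheating_hand_sum(self):
        # 2x2 site: illegit total 1.5, legit total 4.5 -> 0.25
        net = toy_network([[2.0, 1.0], [1.0, 0.5]],
                          [[1.0, 0.0], [0.0, 0.5]])
        assert overall_cheating(net) == pytest.approx(1.5 / 6.0)

    def test_half_illegitimate(self):
        net = toy_network(np.full((2, 2), 1.0), np.full((2, 2), 1.0))
        assert overall_cheating(net) == pytest.approx(0.5)


class TestCheatingFrequency:
    def test_basic_ratio(self):
        net = toy_network([[8.0]], [[2.0]])
        assert cheating_frequency(net, 0) == pytest.approx(0.2)

    def test_pure_cheater(self):
        net = toy_network([[0.0], [0.0]], [[1.0], [2.0]])
        assert cheating_frequency(net, 0) == 1.0

    def test_per_partner_hand_sum(self):
        legit = np.array([[1.0], [2.0], [3.0]])
        illegit = np.array([[0.5], [0.0], [1.5]])
        net = toy_network(legit, illegit)
        assert cheating_frequency(net, 0) == pytest.approx(2.0 / 8.0)
        assert partner_diversity(net, 0) == 3

    def test_unobserved_bird_rejected(self):
        net = toy_network([[1.0, 0.0]], [[0.0, 0.0]])
        with pytest.raises(ValueError):
            cheating_frequency(net, 1)


class TestInnovativeProportion:
    def test_identical_weight_patterns_give_zero(self):
        traits = np.array([[10.0, 5.0], [20.0, 15.0], [30.0, 40.0]])
        w = np.array([1.0, 2.0, 0.5])
        # illegitimate = scaled copy of legitimate -> same density
        assert innovative_proportion(w, 3.0 * w, traits) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_distant_supports_give_one(self):
        traits = np.array([[0.0, 0.0], [1.0, 1.0],
                           [500.0, 500.0], [501.0, 499.0]])
        legit = np.array([1.0, 1.0, 0.0, 0.0])
        illegit = np.array([0.0, 0.0, 1.0, 1.0])
        psi = innovative_proportion(legit, illegit, traits)
        assert psi == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_kernel_sum_oracle(self):
        """Hand-evaluated Gaussian product kernels on a coarse grid."""
        traits = np.array([[0.0, 0.0], [3.0, 1.0]])
        legit = np.array([1.0, 0.5])
        illegit = np.array([0.25, 1.0])
        bw = np.array([1.0, 0.5])
        gridsize, padding = 15, 0.1

        span = traits.max(axis=0) - traits.min(axis=0)
        lo = traits.min(axis=0) - padding * span
        hi = traits.max(axis=0) + padding * span
        gx = np.linspace(lo[0], hi[0], gridsize)
        gy = np.linspace(lo[1], hi[1], gridsize)

        def direct_density(weights):
            dens = np.zeros((gridsize, gridsize))
            for ix, x in enumerate(gx):
                for iy, y in enumerate(gy):
                    for (tx, ty), w in zip(traits, weights):
                        dens[ix, iy] += w * np.exp(
                            -0.5 * ((x - tx) / bw[0]) ** 2
                        ) * np.exp(-0.5 * ((y - ty) / bw[1]) ** 2)
            return dens / dens.sum()

        expected = 1.0 - np.minimum(
            direct_density(legit), direct_density(illegit)
        ).sum()
        got = innovative_proportion(
            legit, illegit, traits, gridsize=gridsize,
            padding=padding, bandwidths=bw,
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_frequency_rescaling(self):
        traits = np.array([[0.0, 0.0], [2.0, 1.0], [8.0, 4.0]])
        legit = np.array([1.0, 0.5, 0.0])
        illegit = np.array([0.0, 0.3, 0.8])
        a = innovative_proportion(legit, illegit, traits)
        b = innovative_proportion(7.0 * legit, 7.0 * illegit, traits)
        assert a == pytest.approx(b, abs=1e-12)

    def test_needs_both_kinds_of_partners(self):
        traits = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            innovative_proportion(
                np.array([1.0, 0.0]), np.array([0.0, 0.0]), traits
            )


class TestGlmTrend:
    def test_constant_half_response_is_flat_on_logit_scale(self):
        df = pd.DataFrame({
            "y": 0.5, "x": np.linspace(-1, 1, 20), "w": 10.0,
        })
        fit = glm_trend(df, "y", ["x"], "w", family="binomial")
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_simulated_logit_slope(self):
        rng = np.random.default_rng(21)
        n, trials = 400, 200
        x = rng.uniform(-2, 2, n)
        p = 1.0 / (1.0 + np.exp(-(0.3 + 0.8 * x)))
        y = rng.binomial(trials, p) / trials
        df = pd.DataFrame({"y": y, "x": x, "w": float(trials)})
        fit = glm_trend(df, "y", ["x"], "w", family="binomial")
        assert abs(fit.params["x"] - 0.8) < 2 * fit.bse["x"]

    def test_matches_independent_irls_to_1e6(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=n)
        w = rng.uniform(5, 50, n)
        p = 1.0 / (1.0 + np.exp(-(0.2 - 1.1 * x)))
        y = np.clip(rng.binomial(50, p) / 50.0, 0.01, 0.99)
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        fit = glm_trend(df, "y", ["x"], "w", family="quasibinomial")
        X = np.column_stack([np.ones(n), x])
        beta = irls_binomial(X, y, w)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_quasibinomial_scales_covariance_by_pearson_dispersion(self):
        rng = np.random.default_rng(30)
        n = 80
        x = rng.normal(size=n)
        w = rng.uniform(10, 100, n)
        y = np.clip(
            1 / (1 + np.exp(-0.5 * x)) + rng.normal(0, 0.1, n), 0.01, 0.99
        )
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        quasi = glm_trend(df, "y", ["x"], "w", family="quasibinomial")
        plain = glm_trend(df, "y", ["x"], "w", family="binomial")
        assert np.allclose(
            quasi.bse.to_numpy(),
            plain.bse.to_numpy() * np.sqrt(quasi.dispersion),
            rtol=1e-8,
        )


class TestRecoveryFromSyntheticData:
    def test_estimated_signs_match_generator_truth(self, field_dataset):
        tt = trend_tests(field_dataset)
        assert tt["overall_cheating_vs_elevation"].params["elevation"] < 0
        assert tt["proportion_cheaters_vs_elevation"].params["elevation"] < 0
        assert tt["cheating_frequency_vs_log_diversity"].params[
            "log_diversity"
        ] < 0

    def test_site_and_bird_tables_are_consistent(self, field_dataset):
        sites = site_estimates(field_dataset)
        birds = bird_estimates(field_dataset)
        assert set(birds["site_id"]) <= set(sites["site_id"])
        assert ((sites["overall_cheating"] >= 0)
                & (sites["overall_cheating"] <= 1)).all()
        assert ((birds["cheating_frequency"] >= 0)
                & (birds["cheating_frequency"] <= 1)).all()
        assert (birds["partner_diversity"] >= 1).all()
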