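"""The Bayesian imputation model: kernels, conjugacy, conservation,
determinism and the smoothing prior."""

import numpy as np
import pytest

from avidiet import (
    CategorySchema,
    DietImputationModel,
    MopModelSpec,
    build_inputs,
    default_truth,
    fit_mop,
    generate_episodes,
    rop_identified_only,
    tally,
)
from avidiet.episodes import CountsTensor
from avidiet.model import (
    DegenerateModelError,
    _softmax_rows,
    _tau_full_conditional,
    sample_lambda,
    sample_latent_items,
    sample_theta,
)

QUICK = MopModelSpec(chains=1, iterations=600, burn_in=200, thinning=2, seed=7)


def tensor(schema, counts):
    return CountsTensor(species="test bird", counts=counts, schema=schema)


class TestBuildInputs:
    def test_splits_unidentified_margin(self, small_schema):
        counts = np.zeros((12, 3, 2), dtype=np.int64)
        counts[2, 2, 0] = 1  # one unidentified at ground in March
        counts[0, 0, 0] = 4
        data = build_inputs(tensor(small_schema, counts))
        assert data.u[2, 0] == 1
        assert data.u.sum() == 1
        assert data.y.sum() == 4

    def test_no_unidentified_gives_zero_margin(self, small_schema):
        counts = np.zeros((12, 3, 2), dtype=np.int64)
        counts[0, 0, 0] = 3
        assert build_inputs(tensor(small_schema, counts)).u.sum() == 0

    def test_all_zero_tensor_rejected(self, small_schema):
        counts = np.zeros((12, 3, 2), dtype=np.int64)
        with pytest.raises(DegenerateModelError):
            build_inputs(tensor(small_schema, counts))


class TestSampleLatentItems:
    def test_assignment_follows_bayes_formula(self):
        # pi=(0.6,0.4); theta rows (0.9,0.1) and (0.2,0.8); at location 1
        # P(item 1) = 0.6*0.9 / (0.6*0.9 + 0.4*0.2) = 0.54/0.62
        rng = np.random.default_rng(0)
        pi = np.tile([0.6, 0.4], (12, 1))
        theta = np.array([[0.9, 0.1], [0.2, 0.8]])
        u = np.zeros((12, 2), dtype=np.int64)
        n = 50_000
        u[0, 0] = n
        w = sample_latent_items(pi, theta, u, rng)
        p = 0.54 / 0.62
        se = np.sqrt(p * (1 - p) / n)
        assert w[0, 0, 0] / n == pytest.approx(p, abs=3 * se)

    def test_point_mass_pi_assigns_everything(self):
        rng = np.random.default_rng(0)
        pi = np.tile([1.0, 0.0], (12, 1))
        theta = np.full((2, 2), 0.5)
        u = np.zeros((12, 2), dtype=np.int64)
        u[3, 1] = 17
        w = sample_latent_items(pi, theta, u, rng)
        assert w[3, 0, 1] == 17 and w[3, 1, :].sum() == 0

    def test_uninformative_theta_follows_pi(self):
        rng = np.random.default_rng(1)
        pi = np.tile([0.3, 0.7], (12, 1))
        theta = np.full((2, 2), 0.5)
        u = np.zeros((12, 2), dtype=np.int64)
        u[0, 0] = 40_000
        w = sample_latent_items(pi, theta, u, rng)
        assert w[0, 0, 0] / 40_000 == pytest.approx(0.3, abs=0.01)

    def test_zero_theta_column_is_degenerate(self):
        rng = np.random.default_rng(0)
        pi = np.tile([0.5, 0.5], (12, 1))
        theta = np.array([[1.0, 0.0], [1.0, 0.0]])
        u = np.zeros((12, 2), dtype=np.int64)
        u[0, 1] = 1
        with pytest.raises(DegenerateModelError):
            sample_latent_items(pi, theta, u, rng)


class TestSampleTheta:
    def test_posterior_mean_is_conjugate(self):
        rng = np.random.default_rng(0)
        counts = np.array([[3, 1]])
        draws = np.stack([sample_theta(1.0, counts, rng) for _ in range(20_000)])
        # Dirichlet(1+3, 1+1) mean = (4/6, 2/6)
        assert draws[:, 0, 0].mean() == pytest.approx(4 / 6, abs=0.01)

    def test_zero_counts_recover_prior(self):
        rng = np.random.default_rng(0)
        draws = np.stack(
            [sample_theta(1.0, np.zeros((1, 3)), rng) for _ in range(20_000)])
        assert np.allclose(draws.mean(axis=0), 1 / 3, atol=0.01)

    def test_large_counts_concentrate(self):
        rng = np.random.default_rng(0)
        counts = np.array([[10_000, 0, 0]])
        theta = sample_theta(1.0, counts, rng)
        assert theta[0, 0] > 0.99


class TestSampleLambda:
    def test_single_month_posterior_tracks_count(self):
        # diffuse priors, informative count in month 0 only: lam ~ count
        rng = np.random.default_rng(3)
        n = np.zeros((12, 1))
        n[0, 0] = 50
        mask = np.zeros(12, dtype=bool)
        mask[0] = True
        x = np.zeros((12, 1))
        tau = np.array([0.01])
        draws = []
        for _ in range(6000):
            x, tau, _ = sample_lambda(
                x, n, tau, mu0=np.log(50.0), s0=5.0, proposal_sd=0.4,
                rng=rng, likelihood_mask=mask)
            draws.append(np.exp(x[0, 0]))
        assert np.mean(draws[1000:]) == pytest.approx(50.0, rel=0.1)

    def test_high_precision_limit_flattens_cycle(self):
        rng = np.random.default_rng(4)
        n = np.tile(np.arange(12)[:, None] % 4 * 5 + 1, (1, 1)).astype(float)
        x = np.log(n + 0.5)
        tau = np.array([1e6])
        for _ in range(3000):
            x, tau, _ = sample_lambda(
                x, n, tau, mu0=1.0, s0=2.0, proposal_sd=0.05, rng=rng)
        assert x[:, 0].std() < 0.05

    def test_circular_prior_rotation_symmetric(self):
        # sum of squared circular increments is rotation-invariant, so the
        # tau full conditional is unchanged by relabelling months
        x = np.random.default_rng(0).normal(size=(12, 2))
        rng_a, rng_b = np.random.default_rng(9), np.random.default_rng(9)
        tau_a = _tau_full_conditional(x, 2.0, 0.5, rng_a)
        tau_b = _tau_full_conditional(np.roll(x, 5, axis=0), 2.0, 0.5, rng_b)
        np.testing.assert_allclose(tau_a, tau_b)

    def test_nan_ratio_raises(self):
        rng = np.random.default_rng(0)
        x = np.full((12, 1), np.nan)
        with pytest.raises(FloatingPointError):
            sample_lambda(x, np.ones((12, 1)), np.array([1.0]),
                          mu0=0.0, s0=1.0, proposal_sd=0.3, rng=rng)


class TestFit:
    def test_same_seed_gives_identical_draws(self, synthetic_counts):
        counts, _ = synthetic_counts
        a = fit_mop(counts, QUICK)
        b = fit_mop(counts, QUICK)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])

    def test_episode_conservation_in_every_draw(self, synthetic_counts):
        counts, _ = synthetic_counts
        res = fit_mop(counts, QUICK)
        totals = res.draws["complete_counts"].sum(axis=-1)
        assert (totals == counts.totals_by_month).all()

    def test_no_unidentified_episodes_mop_equals_identified_rop(self, small_schema):
        counts = np.zeros((12, 3, 2), dtype=np.int64)
        rng = np.random.default_rng(5)
        counts[:, :2, :] = rng.integers(0, 8, size=(12, 2, 2))
        t = tensor(small_schema, counts)
        mop = fit_mop(t, QUICK).mop()
        ropi = rop_identified_only(t)
        np.testing.assert_array_equal(
            np.nan_to_num(mop.values, nan=-1), np.nan_to_num(ropi.values, nan=-1))

    def test_mop_rows_sum_to_one(self, synthetic_counts):
        counts, _ = synthetic_counts
        mop = fit_mop(counts, QUICK).mop()
        assert np.allclose(mop.values[mop.defined].sum(axis=1), 1.0)

    def test_diagnostics_report_rhat_and_ess(self, synthetic_counts):
        counts, _ = synthetic_counts
        spec = MopModelSpec(chains=2, iterations=400, burn_in=100, thinning=2, seed=3)
        diag = fit_mop(counts, spec).diagnostics()
        assert {"parameter", "rhat", "ess"} <= set(diag.columns)
        assert (diag["ess"] > 0).all()

    def test_summary_mentions_species_and_acceptance(self, synthetic_counts):
        counts, _ = synthetic_counts
        res = fit_mop(counts, QUICK)
        text = res.summary()
        assert counts.species in text
        assert "acceptance" in text


def month_variance(results):
    x = results.draws["log_lambda"].mean(axis=(0, 1))
    return float(np.mean(np.var(x, axis=0)))


def test_stronger_smoothing_prior_reduces_seasonal_variance():
    truth = default_truth(seed=21)
    episodes, _ = generate_episodes(truth)
    counts = tally(episodes, truth.species, truth.schema)
    variances = []
    for shape, rate in [(2.0, 2.0), (20.0, 2.0), (2000.0, 2.0)]:
        spec = MopModelSpec(chains=1, iterations=1200, burn_in=400, thinning=2,
                            seed=2, tau_shape=shape, tau_rate=rate)
        variances.append(month_variance(fit_mop(counts, spec)))
    assert variances[0] > variances[1] > variances[2]
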