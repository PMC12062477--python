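"""Growth-rate fitting, aggregation and NRMSE model validation."""

import numpy as np
import pytest

from mscds.mu_estimation import (
    SampleFit,
    aggregate,
    estimate_mu,
    fit_sample,
    nrmse,
    predict_counts,
    residual_sum_of_squares,
    validate_model,
)
from mscds.tile_metrics import DEFAULT_AREA_CM2, TiledObservation
from mscds.synthetic_data import GeneratorConfig, generate_experiment


def obs_from_counts(counts, X_seed=3000.0, S=DEFAULT_AREA_CM2):
    counts = np.asarray(counts)
    times = 24.0 + 6.0 * np.arange(counts.size)
    return TiledObservation(
        sample_id="s", operator="A", X_seed=X_seed, S=S,
        times=times, total_counts=counts.astype(np.int64),
    )


@pytest.mark.parametrize(
    "measured, predicted, expected",
    [
        ([10.0, 20.0], [10.0, 20.0], 0.0),
        ([10.0, 20.0], [8.0, 23.0], 13.0),
        ([7.0], [4.0], 9.0),
    ],
)
def test_residual_sum_of_squares(measured, predicted, expected):
    assert residual_sum_of_squares(measured, predicted) == pytest.approx(expected)


def test_rss_length_mismatch():
    with pytest.raises(ValueError):
        residual_sum_of_squares([1.0], [1.0, 2.0])


def test_fit_recovers_rate_from_noise_free_curve():
    """Inverse crime: data generated by the model itself are recovered exactly."""
    mu_true, alpha, eps, xm = 0.0276, 0.8, 2e-3, 4.0e4
    times = 24.0 + 6.0 * np.arange(33)
    counts = predict_counts(times, 3000.0, DEFAULT_AREA_CM2, mu_true, alpha, eps, xm)
    fit = fit_sample(obs_from_counts(np.round(counts)), alpha, eps, xm)
    assert fit.mu_m_hat == pytest.approx(mu_true, abs=1e-4)
    assert fit.converged


def test_fit_flat_counts_gives_zero_rate():
    x0 = 0.8 * 3000.0
    counts = np.full(33, round(DEFAULT_AREA_CM2 * x0))
    fit = fit_sample(obs_from_counts(counts), 0.8, 0.0, 4.0e4)
    assert abs(fit.mu_m_hat) < 1e-3


def test_fit_never_worse_than_initial_guess():
    rng = np.random.default_rng(5)
    times = 24.0 + 6.0 * np.arange(33)
    base = predict_counts(times, 3000.0, DEFAULT_AREA_CM2, 0.031, 0.8, 2e-3, 4.0e4)
    noisy = np.round(base * rng.lognormal(0, 0.05, base.size))
    obs = obs_from_counts(noisy)
    init = 0.01
    fit = fit_sample(obs, 0.8, 2e-3, 4.0e4, init_mu=init)
    at_init = residual_sum_of_squares(
        noisy, predict_counts(times, 3000.0, DEFAULT_AREA_CM2, init, 0.8, 2e-3, 4.0e4)
    )
    assert fit.rss <= at_init


def test_aggregate_hand_values():
    fits = [SampleFit("a", 0.02, 0.0, 33), SampleFit("b", 0.04, 0.0, 33)]
    est = aggregate(fits)
    assert est.mu_m_mean == pytest.approx(0.03)
    assert est.s == pytest.approx(np.sqrt(2) * 0.01, rel=1e-12)
    assert est.n == 2


def test_aggregate_identical_fits_zero_spread():
    fits = [SampleFit(str(i), 0.025, 0.0, 33) for i in range(5)]
    assert aggregate(fits).s == 0.0


def test_aggregate_requires_two_fits():
    with pytest.raises(ValueError):
        aggregate([SampleFit("a", 0.02, 0.0, 33)])


def test_nrmse_hand_values():
    # one sample, two points, errors (3, 4), range 10
    measured = [[10.0, 0.0]]
    predicted = np.array([7.0, 4.0])
    assert nrmse(measured, predicted) == pytest.approx(100 * np.sqrt(12.5) / 10)
    assert nrmse([[1.0, 5.0]], np.array([1.0, 5.0])) == 0.0


def test_nrmse_scales_inversely_with_range():
    predicted = np.zeros(3)
    a = nrmse([[1.0, 2.0, 5.0]], predicted)
    b = nrmse([[2.0, 4.0, 10.0]], predicted * 2)  # errors and range both doubled
    assert a == pytest.approx(b)
    # fixed errors, doubled range -> halved NRMSE
    c = nrmse([[1.0, 2.0, 5.0], [1.0, 2.0, 9.0]], predicted)
    assert c < a * np.sqrt(2)


def test_nrmse_zero_range_undefined():
    with pytest.raises(ValueError):
        nrmse([[3.0, 3.0]], np.array([1.0, 1.0]))


def test_validate_model_threshold_semantics():
    ok, report = validate_model(
        {
            1500.0: ([[0.0, 10.0]], np.array([0.0, 10.0])),  # perfect
            3000.0: ([[0.0, 10.0]], np.array([1.7, 10.0])),  # ~12% of range
        }
    )
    assert not ok
    assert report[1500.0][1] and not report[3000.0][1]
    assert report[3000.0][0] == pytest.approx(100 * np.sqrt(1.7**2 / 2) / 10)


def test_estimation_recovers_generator_rate_distribution():
    """Across replicated synthetic pre-experiments the estimated mean tracks
    the generator truth and s tracks the injected rate spread."""
    biases, spreads = [], []
    for seed in range(300, 320):
        exp = generate_experiment(GeneratorConfig(seed=seed))
        pre = exp.by_operator()["A"]
        est, _ = estimate_mu(pre)
        truth = exp.truth[exp.truth.operator == "A"].mu_m.mean()
        biases.append((est.mu_m_mean - truth) / truth)
        spreads.append(est.s)
    assert abs(np.mean(biases)) < 0.02
    assert np.mean(spreads) == pytest.approx(1.46e-3, rel=0.30)


def test_noise_free_group_nrmse_is_negligible():
    cfg = GeneratorConfig(seed=3, replicates=2, count_noise_cv=0.0, mu_m_sd=0.0,
                          alpha_concentration=1e7, X_m_sd=0.0, tile_capacity_cv=0.0,
                          dirichlet_concentration=1e7)
    exp = generate_experiment(cfg)
    member = next(
        o for o in exp.observations if o.operator == "A" and o.X_seed == 3000.0
    )
    t = exp.truth.set_index("sample_id").loc[member.sample_id]
    predicted = predict_counts(
        member.times, 3000.0, cfg.S, t.mu_m,
        t.alpha_realized, t.epsilon_realized, t.X_m,
    )
    # rounding to integer counts is the only error source left
    assert nrmse([member.totals.astype(float)], predicted) < 0.05
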