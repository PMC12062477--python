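"""Tile-derived sample parameters: adhesion ratio, heterogeneity, max density."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mscds.tile_metrics import (
    DEFAULT_AREA_CM2,
    N_TILES,
    TiledObservation,
    adhesion_ratio,
    extract_parameters,
    max_cell_density,
    read_observations_csv,
    seeding_heterogeneity,
    write_observations_csv,
)


def make_obs(tile_counts, times=None, X_seed=2000.0, S=DEFAULT_AREA_CM2):
    tile_counts = np.atleast_2d(np.asarray(tile_counts))
    if times is None:
        times = 24.0 + 6.0 * np.arange(tile_counts.shape[0])
    return TiledObservation(
        sample_id="s1", operator="A", X_seed=X_seed, S=S,
        times=np.asarray(times, dtype=float), tile_counts=tile_counts,
    )


def uniform_day1(total):
    assert total % N_TILES == 0
    return np.full(N_TILES, total // N_TILES)


class TestAdhesionRatio:
    def test_full_adhesion(self):
        seeded = DEFAULT_AREA_CM2 * 2000.0
        counts = uniform_day1(64 * int(round(seeded / 64)))
        obs = make_obs([counts], X_seed=counts.sum() / DEFAULT_AREA_CM2)
        assert adhesion_ratio(obs) == pytest.approx(1.0)

    def test_no_adhesion(self):
        obs = make_obs([np.zeros(N_TILES, dtype=int)])
        assert adhesion_ratio(obs) == pytest.approx(0.0)

    def test_hand_value(self):
        counts = np.zeros(N_TILES, dtype=int)
        counts[:7] = 501
        counts[7] = 4
        assert counts.sum() == 3511
        obs = make_obs([counts], X_seed=2000.0, S=2.3409)
        assert adhesion_ratio(obs) == pytest.approx(3511 / (2.3409 * 2000), rel=1e-12)


class TestSeedingHeterogeneity:
    def test_uniform_seeding_is_zero(self):
        obs = make_obs([uniform_day1(6400)])
        assert seeding_heterogeneity(obs) == pytest.approx(0.0, abs=1e-15)

    def test_one_hot_extreme(self):
        counts = np.zeros(N_TILES, dtype=int)
        counts[13] = 1000
        obs = make_obs([counts])
        assert seeding_heterogeneity(obs) == pytest.approx(np.sqrt(63) / 64, rel=1e-12)

    def test_matches_direct_formula(self):
        # fractions (0.5, 0.5/63, ..., 0.5/63), evaluated by brute force
        frac = np.full(N_TILES, 0.5 / 63)
        frac[0] = 0.5
        expected = np.sqrt(np.mean((frac - 1 / 64) ** 2))
        counts = np.round(frac * 63 * 2 * 10000).astype(int)  # integer-exact scaling
        obs = make_obs([counts])
        assert seeding_heterogeneity(obs) == pytest.approx(expected, rel=1e-12)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            seeding_heterogeneity(make_obs([np.zeros(N_TILES, dtype=int)]))
        totals_only = TiledObservation(
            sample_id="s", operator="A", X_seed=2000.0, S=DEFAULT_AREA_CM2,
            times=[24.0], total_counts=[100],
        )
        with pytest.raises(ValueError):
            seeding_heterogeneity(totals_only)

    @given(scale=st.integers(2, 50))
    def test_invariant_to_count_rescaling(self, scale):
        counts = np.arange(1, N_TILES + 1)
        a = seeding_heterogeneity(make_obs([counts]))
        b = seeding_heterogeneity(make_obs([counts * scale]))
        assert a == pytest.approx(b, rel=1e-12)


class TestMaxCellDensity:
    def test_hand_value_single_hot_tile(self):
        counts = np.zeros((1, N_TILES), dtype=int)
        counts[0, 5] = 1000
        obs = make_obs(counts, S=2.3409)
        assert max_cell_density(obs) == pytest.approx(64 * 1000 / 2.3409, rel=1e-12)

    def test_constant_counts_over_time(self):
        row = np.arange(N_TILES)
        obs = make_obs([row, row, row])
        assert max_cell_density(obs) == pytest.approx(64 * row.max() / DEFAULT_AREA_CM2)

    def test_increasing_counts_end_dominates(self):
        rows = [np.full(N_TILES, k) for k in (10, 20, 35)]
        obs = make_obs(rows)
        assert max_cell_density(obs) == pytest.approx(64 * 35 / DEFAULT_AREA_CM2)

    def test_totals_only_requires_uniformity_flag(self):
        obs = TiledObservation(
            sample_id="s", operator="A", X_seed=2000.0, S=1.0,
            times=[24.0, 30.0], total_counts=[100, 250],
        )
        with pytest.raises(ValueError):
            max_cell_density(obs)
        assert max_cell_density(obs, assume_uniform=True) == pytest.approx(250.0)


def test_extract_parameters_uniform_full_adhesion_well():
    total = 64 * 80
    obs = make_obs(
        [uniform_day1(total), uniform_day1(2 * total)],
        X_seed=total / DEFAULT_AREA_CM2,
    )
    p = extract_parameters(obs)
    assert p.alpha == pytest.approx(1.0)
    assert p.epsilon == pytest.approx(0.0, abs=1e-15)
    assert p.X_m == pytest.approx(64 * 160 / DEFAULT_AREA_CM2)


def test_parameter_recovery_from_generator(small_experiment):
    """Measured alpha tracks the generated truth within rounding."""
    truth = small_experiment.truth.set_index("sample_id")
    for obs in small_experiment.observations:
        p = extract_parameters(obs)
        assert p.alpha == pytest.approx(
            truth.loc[obs.sample_id, "alpha"], abs=1.5 / (obs.S * obs.X_seed)
        )
        assert p.epsilon == pytest.approx(
            truth.loc[obs.sample_id, "epsilon_realized"], rel=1e-9
        )


def test_day1_window_enforced():
    counts = np.ones((2, N_TILES), dtype=int)
    obs = make_obs(counts, times=[40.0, 46.0])
    with pytest.raises(ValueError, match="Day 1"):
        _ = obs.day1_index


def test_csv_round_trip(tmp_path, small_experiment):
    path = tmp_path / "obs.csv"
    write_observations_csv(small_experiment.observations, path)
    back = read_observations_csv(path)
    orig = {o.sample_id: o for o in small_experiment.observations}
    assert set(orig) == {o.sample_id for o in back}
    for o in back:
        ref = orig[o.sample_id]
        assert np.array_equal(o.tile_counts, ref.tile_counts)
        assert np.allclose(o.times, ref.times)
        assert o.operator == ref.operator and o.X_seed == ref.X_seed
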