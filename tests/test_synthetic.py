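import numpy as np
import pytest

from mapprofile import (
    ClimateParams,
    GridMeta,
    ToySpeciesLimits,
    auc,
    default_species_presets,
    envelope_model,
    fitness_model,
    hybrid_model,
    make_climate,
    observed_distribution,
    random_binary_map,
    roc_curve,
    standardize,
)
from mapprofile.synthetic import ClimateFields, FitnessParams, GrowthParams


@pytest.fixture(scope="module")
def climate():
    return make_climate(GridMeta(50, 60), seed=123)


class TestMakeClimate:
    def test_deterministic_given_seed(self):
        meta = GridMeta(20, 25)
        c1 = make_climate(meta, seed=9)
        c2 = make_climate(meta, seed=9)
        for f in ("t_cold", "gdd5", "moisture", "mask"):
            np.testing.assert_array_equal(getattr(c1, f), getattr(c2, f))

    def test_different_seed_changes_fields(self):
        meta = GridMeta(20, 25)
        c1 = make_climate(meta, seed=9)
        c2 = make_climate(meta, seed=10)
        assert not np.array_equal(c1.t_cold, c2.t_cold)

    def test_zero_noise_gives_exactly_linear_gradients(self):
        meta = GridMeta(10, 8)
        p = ClimateParams(
            t_cold_noise_sd=0.0, gdd5_noise_sd=0.0, moisture_noise_sd=0.0,
            sea_fraction=0.0,
        )
        c = make_climate(meta, seed=0, params=p)
        # columns identical; rows linear in latitude
        assert (np.ptp(c.t_cold, axis=1) == 0).all()
        diffs = np.diff(c.t_cold[:, 0])
        np.testing.assert_allclose(diffs, diffs[0])

    def test_north_colder_than_south(self, climate):
        assert climate.t_cold[0].mean() < climate.t_cold[-1].mean()

    def test_field_ranges(self, climate):
        assert (climate.gdd5 >= 0).all()
        assert climate.moisture.min() >= 0 and climate.moisture.max() <= 1

    def test_sea_fraction_matches_request(self, climate):
        assert climate.mask.mean() == pytest.approx(0.75, abs=0.02)


class TestEnvelopeModel:
    def test_hard_limit_forces_zero(self, climate):
        lim = default_species_presets()["temperate-like"]
        env = envelope_model(climate, lim)
        cold = climate.t_cold < lim.t_cold_min_s
        assert (env.values[cold] == 0).all()

    def test_core_cell_scores_one_and_half_ramp_scores_half(self):
        meta = GridMeta(1, 2)
        clim = ClimateFields(
            meta=meta,
            t_cold=np.array([[0.0, -18.0]]),  # core / halfway up the cold ramp
            gdd5=np.array([[2000.0, 2000.0]]),
            moisture=np.array([[0.9, 0.9]]),
            mask=np.ones((1, 2), bool),
        )
        lim = ToySpeciesLimits(
            gdd5min_e=500.0, t_cold_min_s=-20.0, t_cold_min_e=-20.0,
            t_cold_max_e=15.0, moisture_min=0.1,
        )
        env = envelope_model(clim, lim)
        assert env.values[0, 0] == pytest.approx(1.0)
        assert env.values[0, 1] == pytest.approx(0.5)

    def test_monotone_into_the_core(self, climate):
        # along the cold ramp the response never decreases with warming
        lim = default_species_presets()["temperate-like"]
        env = envelope_model(climate, lim)
        order = np.argsort(climate.t_cold[climate.mask])
        in_ramp_or_below = (
            climate.t_cold[climate.mask] < lim.t_cold_min_s + 4.0
        )
        # restrict to cells limited only by cold (others in core elsewhere)
        core_other = (
            (climate.gdd5[climate.mask] >= lim.gdd5min_e + 400.0)
            & (climate.moisture[climate.mask] >= lim.moisture_min + 0.15)
            & (climate.t_cold[climate.mask] <= lim.t_cold_max_e - 4.0)
        )
        sel = in_ramp_or_below & core_other
        vals = env.values[climate.mask]
        ramp_vals = vals[order][sel[order]]
        assert (np.diff(ramp_vals) >= -1e-12).all()


class TestHybridModel:
    def test_flag_off_returns_unmasked_growth(self, climate):
        lim = default_species_presets()["temperate-like"]
        lai, growth, _, _ = hybrid_model(
            climate, lim, apply_bioclim_limits=False
        )
        np.testing.assert_array_equal(lai.values, growth.values)

    def test_between_survival_and_establishment_limits(self):
        meta = GridMeta(1, 1)
        clim = ClimateFields(
            meta=meta,
            t_cold=np.array([[-15.0]]),
            gdd5=np.array([[2500.0]]),
            moisture=np.array([[0.8]]),
            mask=np.ones((1, 1), bool),
        )
        lim = ToySpeciesLimits(
            gdd5min_e=500.0, t_cold_min_s=-16.0, t_cold_min_e=-13.0,
            t_cold_max_e=10.0,
        )
        _, _, surv, estab = hybrid_model(clim, lim)
        assert surv.values[0, 0] == 1
        assert estab.values[0, 0] == 0

    def test_nesting_holds_across_random_parameterisations(self, climate):
        rng = np.random.default_rng(31)
        for _ in range(120):
            t_min_s = rng.uniform(-35.0, 0.0)
            t_min_e = t_min_s + rng.uniform(0.0, 6.0)
            t_max_e = t_min_e + rng.uniform(1.0, 30.0)
            lim = ToySpeciesLimits(
                gdd5min_e=rng.uniform(0.0, 2500.0),
                t_cold_min_s=t_min_s,
                t_cold_min_e=t_min_e,
                t_cold_max_e=t_max_e,
                moisture_min=rng.uniform(0.0, 0.6),
            )
            _, growth, surv, estab = hybrid_model(climate, lim)
            g = growth.valid_values() > 0
            s = surv.valid_values().astype(bool)
            e = estab.valid_values().astype(bool)
            assert (e <= s).all() and (s <= g).all()

    def test_limit_ordering_enforced(self):
        with pytest.raises(ValueError):
            ToySpeciesLimits(
                gdd5min_e=100.0, t_cold_min_s=-5.0, t_cold_min_e=-10.0,
                t_cold_max_e=5.0,
            )


class TestFitnessModel:
    def test_fitness_is_the_product_of_components(self, climate):
        fit, comps = fitness_model(climate)
        np.testing.assert_allclose(
            fit.values, comps.survival_p * comps.reproduction_p
        )

    def test_zero_survival_zeroes_fitness(self):
        meta = GridMeta(1, 1)
        clim = ClimateFields(
            meta=meta,
            t_cold=np.array([[-60.0]]),  # far below any frost tolerance
            gdd5=np.array([[4000.0]]),
            moisture=np.array([[1.0]]),
            mask=np.ones((1, 1), bool),
        )
        fit, comps = fitness_model(clim, FitnessParams(frost_steepness=1.0))
        assert comps.survival_p[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert fit.values[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_probabilities_within_unit_interval(self, climate):
        _, comps = fitness_model(climate)
        for arr in (comps.survival_p, comps.reproduction_p, comps.fitness):
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestObservedDistribution:
    def test_no_noise_is_exact_thresholding(self, climate):
        lim = default_species_presets()["temperate-like"]
        env = standardize(envelope_model(climate, lim))
        obs = observed_distribution(env, 0.5, flip_noise=0.0, seed=1)
        np.testing.assert_array_equal(
            obs.values[obs.mask], (env.values[env.mask] >= 0.5).astype(int)
        )

    def test_full_noise_is_exact_complement(self, climate):
        lim = default_species_presets()["temperate-like"]
        env = standardize(envelope_model(climate, lim))
        clean = observed_distribution(env, 0.5, flip_noise=0.0, seed=1)
        flipped = observed_distribution(env, 0.5, flip_noise=1.0, seed=1)
        np.testing.assert_array_equal(
            flipped.values[obs_mask := flipped.mask],
            1 - clean.values[obs_mask],
        )

    def test_deterministic_given_seed(self, climate):
        lim = default_species_presets()["boreal-like"]
        env = standardize(envelope_model(climate, lim))
        o1 = observed_distribution(env, 0.5, 0.2, seed=5)
        o2 = observed_distribution(env, 0.5, 0.2, seed=5)
        np.testing.assert_array_equal(o1.values, o2.values)

    def test_invalid_noise_rejected(self, climate):
        lim = default_species_presets()["boreal-like"]
        env = standardize(envelope_model(climate, lim))
        with pytest.raises(ValueError):
            observed_distribution(env, 0.5, flip_noise=1.5, seed=0)


class TestRandomBinaryMap:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_extremes(self, p, expected):
        m = random_binary_map(GridMeta(10, 10), p, seed=0)
        assert m.values.mean() == expected

    def test_presence_fraction_near_p(self):
        m = random_binary_map(GridMeta(200, 200), 0.5, seed=3)
        # binomial se ~ 0.0025; 8 sigma margin
        assert abs(m.values.mean() - 0.5) < 0.02


class TestSelfConsistency:
    def test_auc_degrades_with_flip_noise(self, climate):
        lim = default_species_presets()["temperate-like"]
        env = standardize(envelope_model(climate, lim))
        noise_levels = [0.0, 0.1, 0.2, 0.3]
        mean_auc = []
        for noise in noise_levels:
            aucs = [
                auc(roc_curve(env, observed_distribution(env, 0.5, noise, seed=s)))
                for s in range(25)
            ]
            mean_auc.append(np.mean(aucs))
        assert mean_auc[0] == pytest.approx(1.0)
        assert all(x > y for x, y in zip(mean_auc, mean_auc[1:]))
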