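"""Error criterion, weighted fitness and grid-search behavior."""

import numpy as np
import pytest

from obtriad.cells import load_pg_parameters
from obtriad.fitting import (
    AlignmentError,
    FIT_PROTOCOL,
    ScheduleError,
    SearchSpace,
    TargetTrace,
    WeightSchedule,
    default_weight_schedule,
    evaluate_space,
    grid_search,
    rms_error,
    simulate_candidate,
    synthesize_target,
    weighted_fitness,
    _apply_combination,
)


def _target(times, v):
    return TargetTrace(times=np.asarray(times, float), v=np.asarray(v, float))


class TestRmsError:
    def test_identical_traces_zero(self):
        t = np.arange(0, 10, 0.05)
        a = _target(t, np.sin(t))
        assert rms_error(a, a) == 0.0

    def test_constant_offset_equals_offset(self):
        t = np.arange(0, 10, 0.05)
        a = _target(t, np.zeros_like(t))
        b = _target(t, np.ones_like(t))
        assert rms_error(a, b) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        t = np.arange(0, 5, 0.05)
        rng = np.random.default_rng(0)
        a = _target(t, rng.normal(size=t.size))
        b = _target(t, rng.normal(size=t.size))
        assert rms_error(a, b) == pytest.approx(rms_error(b, a))

    def test_length_mismatch_rejected(self):
        a = _target(np.arange(5.0), np.zeros(5))
        b = _target(np.arange(4.0), np.zeros(4))
        with pytest.raises(AlignmentError):
            rms_error(a, b)


class TestWeightedFitness:
    def test_uniform_weights_scale_rms(self):
        t = np.arange(0.0, 10.0 + 1e-9, 0.05)
        a = _target(t, np.zeros_like(t))
        b = _target(t, np.sin(t))
        sched = WeightSchedule(((0.0, 10.0, 4.0),), t_total=10.0)
        assert weighted_fitness(a, b, sched) == pytest.approx(2.0 * rms_error(a, b))

    def test_weighting_a_confined_error_region(self):
        # error only inside a window weighted 10 vs 1: fitness scales by
        # sqrt(10) because the weight sits inside the sum, before the root
        t = np.arange(0.0, 30.0, 0.05)
        v = np.zeros_like(t)
        v_model = v.copy()
        window = (t >= 10.0) & (t < 20.0)
        v_model[window] = 1.0
        a = _target(t, v)
        b = _target(t, v_model)
        uniform = WeightSchedule(((0.0, 30.0, 1.0),), t_total=30.0)
        weighted = WeightSchedule(
            ((0.0, 10.0, 1.0), (10.0, 20.0, 10.0), (20.0, 30.0, 1.0)),
            t_total=30.0)
        assert weighted_fitness(a, b, weighted) == pytest.approx(
            np.sqrt(10.0) * weighted_fitness(a, b, uniform))

    def test_zero_difference_zero_fitness(self):
        t = np.arange(0.0, 10.0, 0.05)
        a = _target(t, np.full_like(t, -60.0))
        sched = WeightSchedule(((0.0, 5.0, 1.0), (5.0, 10.0, 10.0)), t_total=10.0)
        assert weighted_fitness(a, a, sched) == 0.0

    def test_sample_outside_schedule_rejected(self):
        t = np.arange(0.0, 20.0, 0.05)
        a = _target(t, np.zeros_like(t))
        sched = WeightSchedule(((0.0, 10.0, 1.0),), t_total=10.0)
        with pytest.raises(ScheduleError):
            weighted_fitness(a, a, sched)

    def test_intervals_must_partition(self):
        with pytest.raises(ValueError):
            WeightSchedule(((0.0, 5.0, 1.0), (6.0, 10.0, 1.0)), t_total=10.0)


class TestSearchSpace:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace({"Mg": (1.0,)})

    def test_size_is_product_of_grids(self):
        space = SearchSpace({"Na": (1.0, 2.0), "CaT": (1.0, 2.0, 3.0)})
        assert space.size == 6
        assert len(list(space.combinations())) == 6


class TestSynthesizeTarget:
    def test_noise_free_target_equals_model_trace(self, pg_params):
        target = synthesize_target(pg_params)
        model = simulate_candidate(pg_params)
        assert np.array_equal(target.v, model[model.labels[0]])
        assert target.provenance == "synthetic"

    def test_same_seed_identical(self, pg_params):
        a = synthesize_target(pg_params, noise_sd=0.5, seed=7)
        b = synthesize_target(pg_params, noise_sd=0.5, seed=7)
        assert np.array_equal(a.v, b.v)


class TestGridSearch:
    def test_single_point_space_returns_it(self, pg_params):
        space = SearchSpace({"CaT": (pg_params.densities["CaT"],)})
        target = synthesize_target(pg_params)
        res = grid_search(space, target, base=pg_params)
        assert res.n_evaluated == 1
        assert res.best_error == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_grid_point_with_zero_error(self, pg_params):
        space = SearchSpace.centered(pg_params, (0.8, 1.0, 1.25),
                                     parameters=("Na", "CaT"))
        plant = {"Na": pg_params.densities["Na"] * 1.25,
                 "CaT": pg_params.densities["CaT"] * 0.8}
        target = synthesize_target(_apply_combination(pg_params, plant))
        res = grid_search(space, target, base=pg_params)
        assert res.best_parameters == pytest.approx(plant)
        assert res.best_error == pytest.approx(0.0, abs=1e-9)

    def test_off_grid_plant_matches_brute_force_argmin(self, pg_params):
        """For a target planted off-grid the search returns the same
        combination as an independent re-evaluation of every grid point."""
        space = SearchSpace.centered(pg_params, (0.85, 1.0, 1.2),
                                     parameters=("Na", "CaT"))
        plant = {"Na": pg_params.densities["Na"] * 1.1,
                 "CaT": pg_params.densities["CaT"] * 0.9}
        target = synthesize_target(_apply_combination(pg_params, plant))
        weights = default_weight_schedule(target)
        res = grid_search(space, target, weights=weights, base=pg_params)
        # oracle: simulate each combination through the slow public path
        best_combo, best_err = None, np.inf
        for combo in space.combinations():
            model = simulate_candidate(_apply_combination(pg_params, combo))
            err = weighted_fitness(target, model, weights)
            if err < best_err:
                best_combo, best_err = combo, err
        assert res.best_parameters == pytest.approx(best_combo)
        assert res.best_error == pytest.approx(best_err, rel=1e-9)

    def test_cached_traces_reproduce_direct_search(self, pg_params):
        space = SearchSpace.centered(pg_params, (0.9, 1.0), parameters=("Na",))
        target = synthesize_target(pg_params, noise_sd=0.3, seed=1)
        cache = evaluate_space(space, base=pg_params)
        direct = grid_search(space, target, base=pg_params)
        cached = grid_search(space, target, base=pg_params, trace_cache=cache)
        assert direct.best_parameters == cached.best_parameters
        assert direct.best_error == pytest.approx(cached.best_error)


class TestDefaultWeightSchedule:
    def test_spike_window_centred_on_target_spike(self, pg_params):
        target = synthesize_target(pg_params)
        sched = default_weight_schedule(target)
        total = sum(hi - lo for lo, hi, _ in sched.intervals)
        assert total == pytest.approx(FIT_PROTOCOL["t_stop"])
        spike_intervals = [iv for iv in sched.intervals if iv[2] == 10.0]
        assert len(spike_intervals) == 1
        lo, hi, _ = spike_intervals[0]
        assert hi - lo == pytest.approx(10.0)
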