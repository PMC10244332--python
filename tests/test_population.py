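"""Population sampling, fractional inhibition, treatment scoring."""

import numpy as np
import pytest

from bh3sim.population import (
    InhibitedSystem,
    TreatmentSpec,
    calibrate_drug_amount,
    compare_survivors,
    death_times_from_traces,
    dose_response,
    lognormal_factors,
    run_treatment,
    sample_population,
    target_occupancy,
    viability_curve,
)
from bh3sim.simulate import simulate


class TestSampler:
    def test_scale_factor_cv_matches_request(self):
        rng = np.random.default_rng(0)
        f = lognormal_factors(0.32, (10_000,), rng)
        assert f.std() / f.mean() == pytest.approx(0.32, abs=0.01)
        assert f.mean() == pytest.approx(1.0, abs=0.01)

    def test_cv_zero_gives_identical_cells(self, bclxl_fixture):
        pop = sample_population(bclxl_fixture.line, n_cells=5, cv=0.0, seed=3)
        for row in pop.initial_states:
            np.testing.assert_array_equal(row, pop.initial_states[0])

    def test_same_seed_reproduces_states(self, bclxl_fixture):
        a = sample_population(bclxl_fixture.line, n_cells=8, seed=42)
        b = sample_population(bclxl_fixture.line, n_cells=8, seed=42)
        np.testing.assert_array_equal(a.initial_states, b.initial_states)

    def test_monomer_totals_scaled_exactly(self, bclxl_fixture):
        line = bclxl_fixture.line
        pop = sample_population(line, n_cells=4, cv=0.32, seed=9)
        # every species scaled per distinct constituent: the single-monomer
        # states of one protein share that protein's factor
        m = line.model
        base = line.fitted_state.state
        i_c, i_m = m.species_index("BCLXL_c"), m.species_index("BCLXL_m")
        ratio_c = pop.initial_states[:, i_c] / base[i_c]
        ratio_m = pop.initial_states[:, i_m] / base[i_m]
        np.testing.assert_allclose(ratio_c, ratio_m, rtol=1e-12)

    def test_invalid_sizes_rejected(self, bclxl_fixture):
        with pytest.raises(ValueError):
            sample_population(bclxl_fixture.line, n_cells=0)
        with pytest.raises(ValueError):
            sample_population(bclxl_fixture.line, cv=-0.1)


class TestInhibition:
    def test_zero_fraction_adds_no_drug(self, bclxl_fixture):
        assert calibrate_drug_amount(bclxl_fixture.line, "BCLXL", 0.0) == 0.0

    def test_full_inhibition_reaches_occupancy_ceiling(self, bclxl_fixture):
        from bh3sim.simulate import steady_state

        line = bclxl_fixture.line
        amount = calibrate_drug_amount(line, "BCLXL", 1.0)
        model = line.effective_model()
        x = np.maximum(line.fitted_state.state, 0.0)
        x[model.species_index("dg_BCLXL")] += amount
        final = simulate(model, x, 500.0).final_state()
        assert target_occupancy(model, final, "BCLXL") >= 0.999

    def test_half_inhibition_hits_half_occupancy(self, bclxl_fixture):
        line = bclxl_fixture.line
        amount = calibrate_drug_amount(line, "BCLXL", 0.5)
        model = line.effective_model()
        x = np.maximum(line.fitted_state.state, 0.0)
        x[model.species_index("dg_BCLXL")] += amount
        final = simulate(model, x, 2000.0).final_state()
        assert target_occupancy(model, final, "BCLXL") == pytest.approx(0.5, abs=0.02)

    def test_unknown_target_rejected(self, bclxl_fixture):
        with pytest.raises(KeyError):
            calibrate_drug_amount(bclxl_fixture.line, "TP53", 0.5)

    def test_fraction_outside_unit_interval_rejected(self, bclxl_fixture):
        with pytest.raises(ValueError):
            calibrate_drug_amount(bclxl_fixture.line, "BCLXL", 1.5)


class TestDeathScoring:
    def test_interpolated_crossing_time(self):
        times = np.arange(0.0, 10.1, 1.0)
        momp = np.where(times < 5.0, 1.0, 1.0 + (times - 4.0))  # crosses 2.0 at t=5
        dt = death_times_from_traces(times, momp[None, :], 2.0)
        assert dt[0] == pytest.approx(5.0, abs=1e-9)

    def test_never_crossing_is_nan(self):
        times = np.linspace(0, 72, 10)
        dt = death_times_from_traces(times, np.ones((3, 10)), 5.0)
        assert np.isnan(dt).all()

    def test_viability_is_survival_fraction(self):
        times = np.linspace(0, 72, 100)
        death = np.full(100, np.nan)
        death[:40] = np.linspace(1, 60, 40)  # 40 of 100 cells die before 72 h
        v = viability_curve(times, death)
        assert v[-1] == pytest.approx(0.60)
        assert v[0] == pytest.approx(1.0)
        assert np.all(np.diff(v) <= 0)

    def test_threshold_is_factor_times_baseline(self, bclxl_fixture):
        pop = sample_population(bclxl_fixture.line, n_cells=4, seed=1)
        spec = TreatmentSpec(targets=[("BCLXL", 0.0)], threshold_factor=1.10)
        res = run_treatment(
            pop, spec, system=InhibitedSystem(line=bclxl_fixture.line, drug_amounts={})
        )
        assert res.threshold == pytest.approx(1.10 * res.baseline, rel=0, abs=0)

    def test_untreated_population_fully_viable(self, bclxl_fixture):
        pop = sample_population(bclxl_fixture.line, n_cells=10, seed=1)
        res = run_treatment(
            pop,
            TreatmentSpec(targets=[("BCLXL", 0.0)]),
            system=InhibitedSystem(line=bclxl_fixture.line, drug_amounts={}),
        )
        assert res.viability_72h == 1.0
        assert res.viability_curve[0] == 1.0

    def test_treatment_spec_validation(self):
        with pytest.raises(ValueError):
            TreatmentSpec(targets=[("BCLXL", 2.0)])
        with pytest.raises(ValueError):
            TreatmentSpec(targets=[("BCLXL", 0.5)], threshold_factor=1.0)
        with pytest.raises(ValueError):
            TreatmentSpec(targets=[("BCLXL", 0.5)], baseline_stat="median")


@pytest.fixture(scope="module")
def grid(bclxl_fixture):
    return dose_response(bclxl_fixture.line, "BCLXL", n_cells=12, seed=3, n_fractions=4)


class TestDoseResponse:
    def test_endpoints_and_shape(self, grid):
        assert grid.fractions[0] == 0.0 and grid.fractions[-1] == 1.0
        assert np.all((grid.viability >= 0) & (grid.viability <= 1))

    def test_zero_dose_matches_untreated_survival(self, grid):
        assert grid.viability[0] == 1.0

    def test_monotone_nonincreasing_with_shared_population(self, grid):
        assert np.all(np.diff(grid.viability) <= 1e-9)


class TestSurvivorContrast:
    def test_sensitive_cells_differ_in_starting_state(self, bcl2_fixture):
        """At a fractional-killing dose, dying cells carry less guardian."""
        line = bcl2_fixture.line
        pop = sample_population(line, n_cells=40, seed=7)
        res = run_treatment(pop, TreatmentSpec(targets=[("MCL1", 0.25)]))
        assert 0.1 < res.viability_72h < 0.95
        table = compare_survivors(pop, res)
        assert {"quantity", "p_value", "q_value", "direction"} <= set(table.columns)
        anti = table[table.quantity == "total_anti_apoptotic"].iloc[0]
        assert anti.direction == "higher_in_surviving"

    def test_no_contrast_without_both_groups(self, bclxl_fixture):
        pop = sample_population(bclxl_fixture.line, n_cells=6, seed=2)
        res = run_treatment(
            pop,
            TreatmentSpec(targets=[("BCLXL", 0.0)]),
            system=InhibitedSystem(line=bclxl_fixture.line, drug_amounts={}),
        )
        with pytest.raises(ValueError, match="no contrast"):
            compare_survivors(pop, res)


class TestNumericalRobustness:
    def test_viability_insensitive_to_solver_tolerance(self, bclxl_fixture):
        """Tightening solver tolerances moves viability by less than half a point."""
        from bh3sim.population import OUTPUT_GRID_H, PRE_RUN_H, calibrate_drug_amount
        from bh3sim.canonical import drug_name

        line = bclxl_fixture.line
        model = line.effective_model()
        pop = sample_population(line, n_cells=12, seed=3)
        amount = calibrate_drug_amount(line, "MCL1", 1.0)
        times = np.arange(0.0, 72.0 + OUTPUT_GRID_H / 2, OUTPUT_GRID_H)
        viability = {}
        for rtol, atol in ((1e-6, 1e-9), (5e-7, 5e-10)):
            baselines, traces = [], []
            for x0 in pop.initial_states:
                naive = simulate(model, x0, PRE_RUN_H, rtol=rtol, atol=atol).final_state()
                baselines.append(naive[model.pore_indices()].sum())
                dosed = naive.copy()
                dosed[model.species_index(drug_name("MCL1"))] += amount
                traj = simulate(model, dosed, 72.0, t_eval=times, rtol=rtol, atol=atol)
                traces.append(traj.momp())
            threshold = 1.10 * max(baselines)
            deaths = death_times_from_traces(times, np.array(traces), threshold)
            viability[rtol] = 1.0 - np.sum(deaths <= 72.0) / len(deaths)
        assert abs(viability[1e-6] - viability[5e-7]) < 0.005 + 1e-12

    def test_dynamics_converge_with_population_size(self, bclxl_fixture):
        """At a common death threshold, a 24-cell and a 96-cell population
        agree within three binomial standard errors (the threshold itself is
        an extreme statistic of the naive sample and is therefore fixed
        here; see the methods note)."""
        line = bclxl_fixture.line
        spec = TreatmentSpec(targets=[("MCL1", 1.0)])
        res_small = run_treatment(sample_population(line, n_cells=24, seed=3), spec)
        res_large = run_treatment(sample_population(line, n_cells=96, seed=4), spec)
        threshold = max(float(np.max(res_small.threshold)), float(np.max(res_large.threshold)))
        v = {}
        for label, res in (("small", res_small), ("large", res_large)):
            deaths = death_times_from_traces(res.times, res.momp_traces, threshold)
            v[label] = 1.0 - np.sum(deaths <= 72.0) / len(deaths)
        se = np.sqrt(max(v["large"] * (1 - v["large"]), 0.25 / 96) / 24)
        assert abs(v["small"] - v["large"]) <= 3 * se


class TestMixedPopulations:
    def test_subclone_replaces_requested_fraction(self, bclxl_fixture):
        from bh3sim.population import mix_populations

        major = sample_population(bclxl_fixture.line, n_cells=10, seed=1)
        minor = sample_population(bclxl_fixture.line, n_cells=10, seed=2)
        mixed = mix_populations(major, minor, 0.3)
        np.testing.assert_array_equal(mixed.initial_states[:3], minor.initial_states[:3])
        np.testing.assert_array_equal(mixed.initial_states[3:], major.initial_states[3:])
        with pytest.raises(ValueError):
            mix_populations(major, minor, 1.5)
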