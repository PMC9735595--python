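"""Synthetic-data generator: kinetics closed form, peak lists, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from plasmalink.kinetics import fit_ic50, fit_one_phase_decay
from plasmalink.quantify import build_xic, integrate_area, isotope_pattern, timecourse
from plasmalink.synthetic import (
    BoundPool,
    SimulationScenario,
    activity_trajectory,
    emit_peaklists,
    ground_truth,
    scenario_from_config,
    scenario_to_config,
    simulate_activity_tables,
    simulate_species_kinetics,
)


class TestScenarioValidation:
    def test_fractions_exceeding_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            SimulationScenario(bound_pools=(
                BoundPool("a", "Cys", 0.7), BoundPool("b", "GSH", 0.5),
            ))

    def test_negative_half_life_rejected(self):
        with pytest.raises(ValueError):
            SimulationScenario(free_degradation_half_life=-1.0)
        with pytest.raises(ValueError):
            SimulationScenario(bound_pools=(BoundPool("a", "Cys", 0.5, -2.0),))

    def test_default_scenario_matches_study_conditions(self):
        scen = SimulationScenario()
        assert scen.sampling_times == (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
        assert scen.net_free_half_life == pytest.approx(1.7)


class TestKineticsClosedForm:
    def test_pure_exponential_without_conversion(self):
        scen = SimulationScenario(
            free_degradation_half_life=9.0, conversion_half_time=None,
            bound_pools=(), sampling_times=(0.0, 9.0, 18.0),
        )
        ab = simulate_species_kinetics(scen)
        free = ab[ab.species == "free"].abundance.to_numpy()
        np.testing.assert_allclose(free, [1.0, 0.5, 0.25], rtol=1e-12)

    def test_conservation_without_degradation(self):
        scen = SimulationScenario(
            free_degradation_half_life=None, conversion_half_time=5.0,
            bound_pools=(BoundPool("a", "Cys", 0.6), BoundPool("b", "crosslink", 0.4)),
        )
        ab = simulate_species_kinetics(scen)
        totals = ab.groupby("time_min").abundance.sum()
        np.testing.assert_allclose(totals, 1.0, rtol=1e-12)

    def test_against_numerical_integrator(self):
        scen = SimulationScenario(
            free_degradation_half_life=2.0, conversion_half_time=4.0,
            bound_pools=(
                BoundPool("a", "Cys", 0.5, 30.0),
                BoundPool("b", "crosslink", 0.3, None),
            ),
            sampling_times=tuple(np.linspace(0, 60, 13)),
        )
        kd, kc = scen.k_degradation, scen.k_conversion

        def rhs(_t, y):
            free, a, b = y
            return [
                -(kd + kc) * free,
                0.5 * kc * free - np.log(2) / 30.0 * a,
                0.3 * kc * free,
            ]

        sol = solve_ivp(rhs, (0, 60), [1.0, 0.0, 0.0],
                        t_eval=scen.sampling_times, rtol=1e-10, atol=1e-12)
        ab = simulate_species_kinetics(scen)
        wide = ab.pivot(index="time_min", columns="species", values="abundance")
        np.testing.assert_allclose(wide["free"], sol.y[0], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(wide["a"], sol.y[1], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(wide["b"], sol.y[2], rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="module")
def clean_scenario():
    return SimulationScenario(
        intensity_cv=0.0, mz_jitter_ppm=0.0, decoys_per_run=0,
        sampling_times=(0.0, 5.0, 10.0, 20.0),
    )


class TestPeaklists:
    def test_noise_free_roundtrip_within_half_percent(self, clean_scenario):
        ab = simulate_species_kinetics(clean_scenario)
        manifest = emit_peaklists(ab, clean_scenario)
        truth = ground_truth(clean_scenario, ab).table
        label_of = {k: v.label for k, v in clean_scenario.candidates().items()}
        course = timecourse(manifest, list(clean_scenario.candidates().values()))
        merged = course.merge(
            truth.assign(label=truth.species.map(label_of)),
            left_on=["time_min", "species"], right_on=["time_min", "label"],
        )
        strong = merged[merged.true_area > 1e3]
        assert len(strong) >= 6
        np.testing.assert_allclose(strong.area, strong.true_area, rtol=5e-3)

    def test_determinism_byte_identical(self):
        scen = SimulationScenario(sampling_times=(0.0, 5.0), seed=11)
        ab = simulate_species_kinetics(scen)
        run1 = emit_peaklists(ab, scen, seed=11)
        run2 = emit_peaklists(ab, scen, seed=11)
        for (t1, p1), (t2, p2) in zip(run1, run2):
            assert t1 == t2
            assert p1.to_csv() == p2.to_csv()

    def test_decoys_only_give_zero_species_xics(self):
        scen = SimulationScenario(
            free_initial_fraction=0.0, bound_pools=(),
            decoys_per_run=200, sampling_times=(0.0, 5.0),
        )
        ab = simulate_species_kinetics(scen)
        manifest = emit_peaklists(ab, scen, seed=3)
        free = SimulationScenario().candidates()["free"]
        pattern = isotope_pattern(free.species.formula(), 2)
        for _t, peaks in manifest:
            trace = build_xic(peaks, pattern.most_intense_mz, 20.0)
            assert integrate_area(trace) == 0.0

    def test_noisy_area_tracks_abundance(self):
        scen = SimulationScenario(seed=5)
        ab = simulate_species_kinetics(scen)
        manifest = emit_peaklists(ab, scen, seed=5)
        course = timecourse(manifest, list(scen.candidates().values()))
        free_label = scen.candidates()["free"].label
        free = course[course.species == free_label].sort_values("time_min")
        fit = fit_one_phase_decay(free.time_min, free.area)
        assert fit.half_life == pytest.approx(scen.net_free_half_life, rel=0.10)


class TestActivityTables:
    CONCS = tuple(10000.0 / 3.0 ** np.arange(8))

    def test_noise_free_tables_recover_trajectory(self):
        trajectory = activity_trajectory([0.0, 9.0, 18.0], half_life=9.0, ic50_0=100.0)
        tables = simulate_activity_tables(trajectory, self.CONCS, cv=0.0, seed=0)
        for (time, true_ic50) in trajectory:
            sub = tables[tables.time_min == time]
            fit = fit_ic50(sub.conc_nM, sub.response_pct)
            assert fit.ic50 == pytest.approx(true_ic50, rel=1e-3)

    def test_ic50_doubling_gives_activity_half_life(self):
        from plasmalink.kinetics import activity_half_life, remaining_activity

        times = [0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0]
        trajectory = [(t, 100.0 * 2.0 ** (t / 9.0)) for t in times]
        tables = simulate_activity_tables(trajectory, self.CONCS, cv=0.0, seed=0)
        fits = {t: fit_ic50(g.conc_nM, g.response_pct) for t, g in tables.groupby("time_min")}
        remaining = [
            (t, remaining_activity(fits[t], fits[0.0]).remaining_pct) for t in times
        ]
        fit = activity_half_life(*zip(*remaining), plateau_mode="fixed-zero")
        assert fit.half_life == pytest.approx(9.0, rel=0.01)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            simulate_activity_tables([(0.0, -5.0)], self.CONCS)


class TestScenarioConfig:
    def test_roundtrip(self):
        scen = SimulationScenario(seed=9, intensity_cv=0.2,
                                  bound_pools=(BoundPool("x", "GSH", 0.4, 45.0),))
        restored = scenario_from_config(scenario_to_config(scen))
        assert restored == scen

    def test_invalid_key_listed(self):
        with pytest.raises(ValueError, match="spray_voltage"):
            scenario_from_config("spray_voltage = 1.5\n")
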