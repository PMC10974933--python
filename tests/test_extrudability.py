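"""Capillary relations, baseline correction and profile extraction."""

import math

import numpy as np
import pytest

from ssepat import (
    ExtrusionTrace,
    FluidParams,
    PlungerProtocol,
    PrintSettings,
    ProfileConfig,
    SystemParams,
    baseline_correct,
    dynamic_viscosity,
    extract_profile,
    flow_rate,
    plunger_speed,
    shear_rate,
    simulate_extrusion_trace,
)
from ssepat.datasets import ta_speed_table
from ssepat.simulate import ValidationError, steady_state_pressure


class TestCapillaryRelations:
    @pytest.mark.parametrize("tps,expected", [(10, 0.010), (20, 0.020), (30, 0.030)])
    def test_plunger_speed_matches_protocol_values(self, tps, expected):
        assert round(plunger_speed(PrintSettings(tps, 0.61), 19.3), 3) == expected

    def test_plunger_speed_equals_tps_when_lh_equals_d(self):
        assert plunger_speed(PrintSettings(7.0, 5.0), 5.0) == pytest.approx(7.0)

    def test_plunger_speed_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            plunger_speed(PrintSettings(10.0), -1.0)
        with pytest.raises(ValidationError):
            PrintSettings(0.0)

    def test_flow_rate_closed_form_and_linearity(self):
        q10 = flow_rate(PrintSettings(10, 0.61))
        assert q10 == pytest.approx(2.9225, abs=5e-4)
        assert flow_rate(PrintSettings(20, 0.61)) == pytest.approx(2 * q10)
        assert flow_rate(PrintSettings(10, 1e-6)) < 1e-10
        # literal legacy reading: print speed times syringe radius
        assert flow_rate(PrintSettings(10, 0.61), 19.3, literal=True) == pytest.approx(96.5)

    def test_shear_rate_values_and_scaling(self):
        g = shear_rate(2.9225, 0.305)
        assert g == pytest.approx(131.2, abs=0.1)
        assert shear_rate(0.0, 0.305) == 0.0
        assert shear_rate(2.9225, 0.61) == pytest.approx(g / 8.0)
        with pytest.raises(ValidationError):
            shear_rate(1.0, 0.0)

    def test_dynamic_viscosity_closed_form(self):
        mu = dynamic_viscosity(1.0, 2.9225, 25.0, 0.61, 292.6)
        assert mu == pytest.approx(0.159, abs=5e-4)
        assert dynamic_viscosity(0.0, 2.9225, 25.0, 0.61, 292.6) == 0.0
        assert dynamic_viscosity(1.0, 2 * 2.9225, 25.0, 0.61, 292.6) == pytest.approx(mu / 2)
        with pytest.raises(ValidationError):
            dynamic_viscosity(1.0, 0.0, 25.0, 0.61, 292.6)


class TestBaselineCorrect:
    def _run(self, system, fluid, tps=10, seed=0):
        protocol = PlungerProtocol.compression_cycle(tps)
        return simulate_extrusion_trace(fluid, system, protocol, seed=seed)

    def test_self_correction_is_zero(self, system, fluid):
        trace = self._run(system, fluid)
        corrected = baseline_correct(trace, trace)
        assert np.all(corrected.pressure == 0.0)

    def test_zero_baseline_is_identity(self, system, fluid):
        trace = self._run(system, fluid)
        zero = ExtrusionTrace(time=trace.time, pressure=np.zeros_like(trace.time),
                              displacement=trace.displacement)
        corrected = baseline_correct(trace, zero)
        # unchanged except for the documented clip at zero
        assert np.array_equal(corrected.pressure, np.clip(trace.pressure, 0, None))

    def test_duration_mismatch_raises(self, system, fluid):
        trace = self._run(system, fluid, tps=10)
        other = self._run(system, None, tps=20)
        with pytest.raises(ValidationError, match="duration"):
            baseline_correct(trace, other)

    def test_friction_pair_recovers_internal_pressure(self, system, fluid):
        """Fluid run minus its paired friction-only run recovers the
        simulator's internal (friction-free) steady pressure within 2%."""
        trace = self._run(system, fluid, seed=5)
        base = self._run(system, None, seed=6)
        corrected = baseline_correct(trace, base)
        comp = trace.time < 500.0
        steady = comp & (trace.time > 400.0)
        assert np.mean(corrected.pressure[steady]) == pytest.approx(
            np.mean(trace.internal_pressure[steady]), rel=0.02)


def make_piecewise_trace(k=350.0, p_star=400.0, speed=0.01, fs=10.0):
    """Ideal ramp-then-plateau trace: linear in displacement with slope k up
    to p_star, then an exact plateau, followed by a stationary hold."""
    t_ramp = np.arange(1, int(180 * fs) + 1) / fs
    x_ramp = speed * t_ramp
    p = np.minimum(k * x_ramp, p_star)
    t_hold = t_ramp[-1] + np.arange(1, int(60 * fs) + 1) / fs
    x_hold = np.full_like(t_hold, x_ramp[-1])
    return ExtrusionTrace(
        time=np.concatenate([t_ramp, t_hold]),
        pressure=np.concatenate([p, np.full_like(t_hold, p_star)]),
        displacement=np.concatenate([x_ramp, x_hold]),
    )


class TestExtractProfile:
    def test_ideal_piecewise_trace(self, system):
        cfg = ProfileConfig()
        trace = make_piecewise_trace(k=350.0, p_star=400.0)
        prof = extract_profile(trace, system, PrintSettings(10), cfg)
        assert prof.yield_point == pytest.approx(400.0, rel=cfg.rel_tol)
        assert prof.young_modulus == pytest.approx(350.0, rel=0.02)
        assert prof.pressure_flow_cessation == pytest.approx(400.0, abs=1e-9)

    def test_max_pressure_of_monotone_trace_is_last_compression_sample(self, system):
        fs = 10.0
        t = np.arange(1, 1201) / fs
        x = np.where(t <= 60, 0.01 * t, 0.6)
        # ramp that bends at ~300 kPa mid-compression but keeps creeping up
        p_comp = np.minimum(10.0 * t, 300.0 + 0.2 * t)
        p = np.where(t <= 60, p_comp, 250.0)
        trace = ExtrusionTrace(time=t, pressure=p, displacement=x)
        prof = extract_profile(trace, system, PrintSettings(10))
        comp_last = p[t <= 60][-1]
        assert prof.max_pressure == pytest.approx(comp_last)

    def test_parameter_recovery_from_simulation(self, system):
        """Yield pressure recovered within 5% and apparent viscosity within
        10% of the simulator's analytic steady value."""
        fluid = FluidParams(yield_pressure=400.0, flow_index_n=0.4)
        settings = PrintSettings(20)
        protocol = PlungerProtocol.compression_cycle(20)
        trace = simulate_extrusion_trace(fluid, system, protocol, seed=42)
        base = simulate_extrusion_trace(None, system, protocol, seed=43)
        prof = extract_profile(baseline_correct(trace, base), system, settings)
        assert prof.yield_point == pytest.approx(400.0, rel=0.05)
        p_ss = steady_state_pressure(fluid, system,
                                     plunger_speed(settings, system.syringe_inner_diameter))
        stress_analytic = (p_ss * system.syringe_area / 1000.0
                           / (math.pi * system.nozzle_radius**2) * 1000.0)
        visc_analytic = stress_analytic / prof.shear_rate
        assert prof.apparent_viscosity == pytest.approx(visc_analytic, rel=0.10)

    def test_stress_viscosity_shear_rate_identity(self, system, fluid):
        protocol = PlungerProtocol.compression_cycle(10)
        trace = simulate_extrusion_trace(fluid, system, protocol, seed=1)
        prof = extract_profile(trace, system, PrintSettings(10))
        assert prof.apparent_viscosity * prof.shear_rate == pytest.approx(
            prof.shear_stress_steady, rel=1e-12)

    def test_capillary_wall_convention_switch(self, system, fluid):
        protocol = PlungerProtocol.compression_cycle(10)
        trace = simulate_extrusion_trace(fluid, system, protocol, seed=1)
        prof = extract_profile(trace, system, PrintSettings(10),
                               ProfileConfig(stress_convention="capillary-wall"))
        # wall stress = steady pressure * r / (2L), far below the nozzle-area figure
        steady = trace.pressure[(trace.time > 400) & (trace.time < 500)].mean()
        expected = steady * system.nozzle_radius / (2 * system.nozzle_length)
        assert prof.shear_stress_steady == pytest.approx(expected, rel=0.02)

    def test_yield_undetected_on_pure_line(self, system):
        t = np.arange(1, 601) / 10.0
        x0 = 0.01 * t
        trace = ExtrusionTrace(
            time=np.concatenate([t, t[-1] + t]),
            pressure=np.concatenate([350 * x0, np.full_like(t, 350 * x0[-1])]),
            displacement=np.concatenate([x0, np.full_like(t, x0[-1])]),
        )
        # plateau after ramp counts as departure; a never-departing line errors
        from ssepat.extrudability import YieldUndetectedError
        pure = ExtrusionTrace(time=t, pressure=350 * x0, displacement=x0)
        with pytest.raises((YieldUndetectedError, ValidationError)):
            extract_profile(pure, system, PrintSettings(10))


@pytest.fixture(scope="module")
def profiles(system, fluid):
    out = {}
    for i, tps in enumerate((10, 20, 30)):
        protocol = PlungerProtocol.compression_cycle(tps)
        trace = simulate_extrusion_trace(fluid, system, protocol, seed=20 + i)
        base = simulate_extrusion_trace(None, system, protocol, seed=50 + i)
        out[tps] = extract_profile(baseline_correct(trace, base), system,
                                   PrintSettings(tps))
    return out


class TestSpeedEffects:

    def test_yield_point_speed_invariant_but_yield_time_drops(self, profiles):
        yields = [profiles[s].yield_point for s in (10, 20, 30)]
        spread = (max(yields) - min(yields)) / np.mean(yields)
        assert spread <= 0.05
        times = [profiles[s].yield_time for s in (10, 20, 30)]
        assert times[0] > times[1] > times[2]

    def test_max_pressure_rises_and_viscosities_fall_with_speed(self, profiles):
        maxes = [profiles[s].max_pressure for s in (10, 20, 30)]
        assert maxes[0] < maxes[1] < maxes[2]
        for attr in ("apparent_viscosity", "dynamic_viscosity"):
            vals = [getattr(profiles[s], attr) for s in (10, 20, 30)]
            assert vals[0] > vals[1] > vals[2]


def test_reference_table_stress_viscosity_ratio_scales_with_speed():
    """In the published texture-analyzer table the ratio steady-stress /
    apparent-viscosity (= shear rate) scales 1:2:3 with print speed within
    10% for every formulation."""
    table = ta_speed_table()
    for form, group in table.groupby("formulation"):
        ratios = (group["shear_stress_steady"] / group["apparent_viscosity"])
        base = ratios.loc[(form, 10)]
        assert ratios.loc[(form, 20)] / base == pytest.approx(2.0, rel=0.10)
        assert ratios.loc[(form, 30)] / base == pytest.approx(3.0, rel=0.10)
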