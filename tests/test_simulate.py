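"""Simulator physics: baselines, closed-form limits, conservation, events."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssepat import (
    BurgersParams,
    EventSpec,
    FluidParams,
    GelParams,
    PlungerProtocol,
    ProtocolStep,
    SystemParams,
    simulate_extrusion_trace,
    simulate_rheometer,
    render_batch_image,
    design_batch,
)
from ssepat.simulate import ValidationError, steady_state_pressure


def constant_push(speed=0.01, distance=3.0, fs=10.0):
    return PlungerProtocol(steps=(ProtocolStep(speed, distance=distance),),
                           sampling_rate=fs)


class TestExtrusionTrace:
    def test_empty_syringe_baseline_is_friction_only(self):
        system = SystemParams(friction_force=2.0, noise_sd=0.5)
        trace = simulate_extrusion_trace(None, system, constant_push(), seed=0)
        assert np.allclose(trace.pressure, system.friction_pressure, atol=5 * 0.5)
        assert np.all(trace.extruded_mass == 0.0)

    def test_stationary_plunger_builds_no_pressure(self):
        system = SystemParams(noise_sd=0.2)
        protocol = PlungerProtocol(steps=(ProtocolStep(0.0, hold_duration=30.0),))
        trace = simulate_extrusion_trace(FluidParams(yield_pressure=400.0), system,
                                         protocol, seed=1)
        assert np.all(trace.internal_pressure == 0.0)
        assert np.max(trace.pressure) < system.friction_pressure + 5 * 0.2
        assert trace.extruded_mass[-1] == 0.0

    def test_newtonian_steady_state_matches_hagen_poiseuille(self, quiet_system):
        """At steady flow of a Newtonian fluid the internal pressure equals
        the closed-form Hagen-Poiseuille drop for Q = v * A_syringe."""
        mu = 2.0
        fluid = FluidParams(yield_pressure=0.0, consistency_K=mu, flow_index_n=1.0)
        trace = simulate_extrusion_trace(fluid, quiet_system,
                                         constant_push(0.01, 3.0, fs=20.0), seed=0)
        q = 0.01 * quiet_system.syringe_area
        r = quiet_system.nozzle_radius
        dp_kpa = 8.0 * mu * quiet_system.nozzle_length * q / (math.pi * r**4) / 1000.0
        assert trace.internal_pressure[-1] == pytest.approx(dp_kpa, rel=0.01)

    def test_mass_conservation(self, quiet_system):
        """Extruded mass never exceeds swept volume; with no yield stress and
        a long decompression hold the two agree within 1%."""
        fluid = FluidParams(yield_pressure=0.0, consistency_K=5.0, flow_index_n=0.4)
        protocol = PlungerProtocol(
            steps=(ProtocolStep(0.01, distance=4.0),
                   ProtocolStep(0.0, hold_duration=120.0)),
        )
        trace = simulate_extrusion_trace(fluid, quiet_system, protocol, seed=0)
        swept = fluid.density * quiet_system.syringe_area * 4.0
        assert trace.extruded_mass[-1] <= swept * (1 + 1e-9)
        assert trace.extruded_mass[-1] == pytest.approx(swept, rel=0.01)

    @pytest.mark.parametrize("speeds", [(0.01, 0.02, 0.03)])
    def test_steady_pressure_increases_with_plunger_speed(self, quiet_system, speeds):
        fluid = FluidParams()
        finals = [
            simulate_extrusion_trace(fluid, quiet_system,
                                     constant_push(v, 5.0), seed=0).internal_pressure[-1]
            for v in speeds
        ]
        assert finals[0] < finals[1] < finals[2]
        # and the integrator converges to the analytic steady state
        for v, p in zip(speeds, finals):
            assert p == pytest.approx(steady_state_pressure(fluid, quiet_system, v),
                                      rel=0.01)

    def test_clog_raises_and_bubble_lowers_pressure(self, system, fluid):
        protocol = constant_push(0.02, 5.0)
        base = simulate_extrusion_trace(fluid, system, protocol, seed=7)
        clog = simulate_extrusion_trace(
            fluid, system, protocol,
            events=[EventSpec("clog", 150.0, 0.5, 20.0)], seed=7)
        assert np.max(clog.internal_pressure) > np.max(base.internal_pressure) + 20
        bubble = simulate_extrusion_trace(
            fluid, system, protocol,
            events=[EventSpec("bubble", 150.0, 1.0, 15.0)], seed=7)
        window = (base.time >= 150.0) & (base.time <= 165.0)
        assert np.all(bubble.internal_pressure[window]
                      < base.internal_pressure[window] - 50)

    def test_determinism_bit_for_bit(self, system, fluid):
        a = simulate_extrusion_trace(fluid, system, constant_push(), seed=11)
        b = simulate_extrusion_trace(fluid, system, constant_push(), seed=11)
        assert np.array_equal(a.pressure, b.pressure)
        assert np.array_equal(a.extruded_mass, b.extruded_mass)
        c = simulate_extrusion_trace(fluid, system, constant_push(), seed=12)
        assert not np.array_equal(a.pressure, c.pressure)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(yield_pressure=-1.0), dict(consistency_K=0.0),
         dict(flow_index_n=0.0), dict(flow_index_n=2.0), dict(density=-0.1)],
    )
    def test_fluid_validation(self, kwargs):
        with pytest.raises(ValidationError):
            FluidParams(**kwargs)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValidationError):
            PlungerProtocol(steps=())
        with pytest.raises(ValidationError):
            ProtocolStep(0.01)  # neither distance nor hold

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(speed=st.floats(0.005, 0.05), seed=st.integers(0, 2**20))
    def test_trace_invariants_hold_for_any_run(self, speed, seed):
        system = SystemParams()
        trace = simulate_extrusion_trace(
            FluidParams(), system, constant_push(speed, 2.0), seed=seed)
        assert np.all(np.diff(trace.time) > 0)
        assert np.all(np.diff(trace.extruded_mass) >= 0)
        assert trace.extruded_mass[-1] <= (
            FluidParams().density * system.syringe_area * 2.0 * (1 + 1e-9))


class TestRheometerSim:
    def test_gel_has_storage_above_loss_everywhere(self):
        fq, amp, _ = simulate_rheometer(GelParams(loss_ratio=0.3), BurgersParams(),
                                        seed=0)
        assert (fq["G_prime_Pa"] > fq["G_double_prime_Pa"]).all()
        assert (amp["G_prime_Pa"].iloc[:10] > amp["G_double_prime_Pa"].iloc[:10]).all()

    def test_purely_elastic_creep_recovers_fully(self):
        from ssepat.rheology import CreepTrace, creep_summary
        _, _, creep = simulate_rheometer(
            GelParams(), BurgersParams(eta1=None, eta2=2.0e4), seed=1)
        cycles = creep_summary(CreepTrace.from_frame(creep))
        for c in cycles:
            assert c.recovered_pct == pytest.approx(100.0, abs=1.0)

    def test_burgers_unrecovered_strain_matches_analytic(self):
        """Residual strain per cycle equals stress*t_on/eta1 (steady-flow
        branch of the Burgers compliance) within 2%."""
        from ssepat.rheology import CreepTrace, creep_summary
        params = BurgersParams(eta1=2.0e6)
        _, _, creep = simulate_rheometer(GelParams(), params, seed=2)
        cycles = creep_summary(CreepTrace.from_frame(creep))
        expected = 500.0 * 60.0 / params.eta1
        for c in cycles:
            assert c.residual_strain - c.initial_strain == pytest.approx(
                expected, rel=0.02)

    def test_non_positive_modulus_rejected(self):
        with pytest.raises(ValidationError):
            GelParams(plateau_modulus=0.0)
        with pytest.raises(ValidationError):
            BurgersParams(E1=-1.0)


class TestBatchImage:
    def test_sixty_printlets_render_sixty_components(self):
        from skimage import measure
        batch, _ = design_batch()
        img, truth = render_batch_image(batch, pixel_scale=4.0, noise_sd=0.0)
        labels = measure.label(img > 128)
        assert labels.max() == len(batch.printlets) == 70
        assert len(truth) == 70

    def test_empty_batch_renders_blank(self):
        from ssepat.gcode import BatchModel
        img, truth = render_batch_image(
            BatchModel(printlets=[], layer_height=0.61, spacing=10.0))
        assert img.max() == 0
        assert len(truth) == 0

    def test_single_disk_pixel_diameter(self):
        from ssepat.gcode import BatchModel, Printlet
        batch = BatchModel(
            printlets=[Printlet("P1", 0.0, 0.0, 6.0, 2.4, 10.0)],
            layer_height=0.61, spacing=10.0)
        img, truth = render_batch_image(batch, pixel_scale=10.0, noise_sd=0.0)
        assert truth["diameter_mm"].iloc[0] == pytest.approx(12.0)
        cols = np.any(img > 128, axis=0)
        width_px = int(cols.sum())
        assert abs(width_px - 120) <= 1
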