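"""Photocycle propagation: conservation, oracles, saturation, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mermaidkin import kinetics, synth
from mermaidkin.kinetics import KineticScheme, LightProtocol


def simple_cycle(sigma=1.0, k_close=1 / 2.7e-3, k_rec=1 / 1.21):
    return KineticScheme(
        state_names=("C", "O", "Dst"),
        conducting_mask=(False, True, False),
        ground_state="C",
        photo_rates={("C", "O"): sigma},
        thermal_rates={("O", "Dst"): k_close, ("Dst", "C"): k_rec},
    )


class TestSchemeValidation:
    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError, match="negative"):
            KineticScheme(("A", "B"), (False, True), "A", thermal_rates={("A", "B"): -1.0})

    def test_rejects_self_transition(self):
        with pytest.raises(ValueError, match="self-transition"):
            KineticScheme(("A", "B"), (False, True), "A", thermal_rates={("A", "A"): 1.0})

    def test_rejects_unknown_state(self):
        with pytest.raises(ValueError, match="unknown"):
            KineticScheme(("A", "B"), (False, True), "A", photo_rates={("A", "X"): 1.0})

    def test_generator_columns_sum_to_zero(self, ephys_scheme):
        for intensity in (0.0, 1.0, 1e4):
            g = ephys_scheme.generator(intensity)
            assert np.allclose(g.sum(axis=0), 0.0, atol=1e-12)


class TestProtocolValidation:
    def test_rejects_overlapping_segments(self):
        with pytest.raises(ValueError, match="overlap"):
            LightProtocol(segments=((0.0, 1.0, 1.0), (0.5, 2.0, 1.0)))

    def test_rejects_reversed_segment(self):
        with pytest.raises(ValueError):
            LightProtocol(segments=((1.0, 0.5, 1.0),))

    def test_rejects_bad_excited_fraction(self):
        with pytest.raises(ValueError):
            LightProtocol(delta_flash=(0.0, 1.5))


class TestPropagate:
    def test_dark_stays_in_ground_state(self, ephys_scheme):
        traj = kinetics.propagate(ephys_scheme, LightProtocol(), np.linspace(0, 10, 50))
        assert np.allclose(traj.state("D"), 1.0, atol=1e-12)

    def test_rejects_non_increasing_grid(self, ephys_scheme):
        with pytest.raises(ValueError, match="increasing"):
            kinetics.propagate(ephys_scheme, LightProtocol(), np.array([0.0, 1.0, 1.0]))

    def test_conservation_under_step_protocol(self, ephys_scheme):
        protocol = LightProtocol(segments=((0.0, 0.5, 1e3),))
        grid = np.linspace(0.0, 1.0, 2000)
        traj = kinetics.propagate(ephys_scheme, protocol, grid)
        assert np.all(np.abs(traj.occupancy.sum(axis=1) - 1.0) <= 1e-9)
        assert np.all(traj.occupancy >= 0.0)

    def test_flash_open_state_peaks_at_350_us(self, ephys_scheme, flash_trajectory):
        f = flash_trajectory.conducting(ephys_scheme)
        t_peak = flash_trajectory.times[np.argmax(f)]
        assert t_peak == pytest.approx(350e-6, rel=1e-3)

    def test_matches_ode_oracle(self, ephys_scheme):
        """Piecewise matrix exponential vs stiff ODE integration <= 1e-7."""
        protocol = LightProtocol(segments=((0.0, 0.2, 500.0), (0.3, 0.5, 2000.0)))
        grid = np.linspace(0.0, 0.6, 301)
        traj = kinetics.propagate(ephys_scheme, protocol, grid)

        def rhs(t, p):
            return ephys_scheme.generator(protocol.intensity_at(t)) @ p

        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        sol = solve_ivp(rhs, (0.0, 0.6), p0, t_eval=grid, method="LSODA",
                        rtol=1e-11, atol=1e-13, max_step=0.05)
        assert np.max(np.abs(sol.y.T - traj.occupancy)) <= 1e-7

    def test_long_time_step_reaches_steady_state(self, three_state):
        intensity = 50.0
        protocol = LightProtocol(segments=((0.0, 500.0, intensity),))
        traj = kinetics.propagate(three_state, protocol, np.array([0.0, 250.0, 500.0]))
        ss = kinetics.steady_state(three_state, intensity)
        assert np.max(np.abs(traj.occupancy[-1] - ss)) <= 1e-8

    def test_flash_decay_is_mono_exponential(self, ephys_scheme, flash_trajectory):
        """Open-state decay after the fast feed ends follows exp(-t/2.7ms)."""
        from mermaidkin.ephys import fit_exponentials

        t = flash_trajectory.times
        f = flash_trajectory.conducting(ephys_scheme)
        sel = t >= 3e-3  # fast component fully decayed (~30 opening lifetimes)
        fit = fit_exponentials(t[sel], f[sel], 1)
        assert fit.taus[0] == pytest.approx(2.7e-3, rel=1e-4)
        assert fit.residual_rms < 1e-10


class TestSteadyState:
    def test_zero_intensity_is_ground_point_mass(self, ephys_scheme):
        ss = kinetics.steady_state(ephys_scheme, 0.0)
        assert ss[ephys_scheme.index("D")] == pytest.approx(1.0)

    def test_three_state_closed_form(self):
        """O_ss = (a/kc) / (1 + a/kc + a/kr) for the C->O->Dst->C cycle."""
        a, kc, kr = 7.0, 1 / 2.7e-3, 1 / 1.21
        scheme = simple_cycle(sigma=1.0, k_close=kc, k_rec=kr)
        ss = kinetics.steady_state(scheme, a)
        expected = (a / kc) / (1.0 + a / kc + a / kr)
        assert ss[1] == pytest.approx(expected, rel=1e-10)

    def test_saturating_limit(self):
        kc, kr = 1 / 2.7e-3, 1 / 1.21
        scheme = simple_cycle(k_close=kc, k_rec=kr)
        ss = kinetics.steady_state(scheme, 1e9)
        assert ss[1] == pytest.approx(kr / (kr + kc), rel=1e-4)
        assert kr / (kr + kc) == pytest.approx(2.23e-3, rel=2e-3)

    def test_saturation_ratio_non_increasing_in_intensity(self, three_state):
        """Stationary/peak open-state ratio decreases with light intensity."""
        ratios = []
        for intensity in np.geomspace(1.0, 1e5, 6):
            protocol = LightProtocol(segments=((0.0, 20.0, intensity),))
            grid = np.unique(np.concatenate([
                np.linspace(0, 0.1, 2001), np.linspace(0.1, 20.0, 400)]))
            traj = kinetics.propagate(three_state, protocol, grid)
            f = traj.conducting(three_state)
            ratios.append(f[-1] / f.max())
        assert np.all(np.diff(ratios) <= 1e-12)


class TestCurrentConversion:
    def test_zero_at_reversal(self, ephys_scheme, flash_trajectory):
        trace = kinetics.current_from_occupancy(flash_trajectory, ephys_scheme, -5.7, -5.7, 10.0)
        assert np.allclose(trace.current, 0.0)

    def test_sign_flips_across_reversal(self, ephys_scheme, flash_trajectory):
        below = kinetics.current_from_occupancy(flash_trajectory, ephys_scheme, -60.0, -5.7, 10.0)
        above = kinetics.current_from_occupancy(flash_trajectory, ephys_scheme, +40.0, -5.7, 10.0)
        assert below.current.min() < 0 and np.all(below.current <= 0)
        assert above.current.max() > 0 and np.all(above.current >= 0)

    def test_monotone_in_voltage(self, ephys_scheme, flash_trajectory):
        currents = [
            kinetics.current_from_occupancy(flash_trajectory, ephys_scheme, v, -5.7, 10.0)
            .current[17500]
            for v in (-80.0, -40.0, 0.0, 40.0)
        ]
        assert np.all(np.diff(currents) > 0)

    def test_inward_at_minus_60(self, ephys_scheme, flash_trajectory):
        trace = kinetics.current_from_occupancy(
            flash_trajectory, ephys_scheme, -60.0, -5.713904, 10.0
        )
        assert trace.current.min() < -1.0


class TestDoublePulse:
    def test_ratio_approaches_one_at_long_intervals(self, ephys_scheme):
        _, ratios = kinetics.double_pulse_recovery(
            ephys_scheme, 0.3, 1e4, [30.0], dt=5e-4
        )
        assert ratios[0] == pytest.approx(1.0, abs=1e-3)

    def test_ratios_monotone_and_bounded(self, ephys_scheme):
        _, ratios = kinetics.double_pulse_recovery(
            ephys_scheme, 0.3, 1e4, [0.2, 0.5, 1.0, 2.0, 5.0], dt=5e-4
        )
        assert np.all(np.diff(ratios) > 0)
        assert np.all((ratios > 0) & (ratios <= 1.0))

    def test_single_interval_at_tau_gives_1_minus_e(self):
        """With near-complete desensitization, ratio(tau_rec) ~ 1 - 1/e."""
        scheme = simple_cycle(sigma=1.0, k_close=1 / 2.7e-3, k_rec=1 / 1.21)
        _, ratios = kinetics.double_pulse_recovery(scheme, 0.5, 1e4, [1.21], dt=2e-4)
        assert ratios[0] == pytest.approx(1.0 - np.exp(-1.0), abs=0.01)

    def test_empty_interval_list_rejected(self, ephys_scheme):
        with pytest.raises(ValueError, match="empty"):
            kinetics.double_pulse_recovery(ephys_scheme, 0.3, 1e4, [])


@settings(max_examples=20, deadline=None)
@given(
    sigma=st.floats(0.1, 100.0),
    k_close=st.floats(1.0, 1e3),
    k_rec=st.floats(0.05, 10.0),
    intensity=st.floats(0.0, 100.0),
)
def test_conservation_property(sigma, k_close, k_rec, intensity):
    """Total occupancy stays at 1 (<=1e-9 drift) for random cycles/intensities."""
    scheme = simple_cycle(sigma, k_close, k_rec)
    protocol = LightProtocol(segments=((0.0, 0.5, intensity),))
    traj = kinetics.propagate(scheme, protocol, np.linspace(0.0, 1.0, 200))
    assert np.all(np.abs(traj.occupancy.sum(axis=1) - 1.0) <= 1e-9)
    assert np.all(traj.occupancy >= 0.0)


def test_discretize_ramp_segments_cover_interval():
    protocol = kinetics.discretize_ramp(0.0, 0.01, lambda t: 100.0 * t, step=1e-3)
    assert len(protocol.segments) == 10
    assert protocol.segments[0][0] == 0.0 and protocol.segments[-1][1] == pytest.approx(0.01)
    mids = [0.5 * (a + b) for a, b, _ in protocol.segments]
    assert protocol.segments[3][2] == pytest.approx(100.0 * mids[3])
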