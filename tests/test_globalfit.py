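"""Global lifetime analysis: grids, Bateman kinetics, SVD, varpro fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mermaidkin import globalfit, synth
from mermaidkin.globalfit import (
    TimeResolvedSpectra,
    bateman_coefficients,
    bateman_concentrations,
    eads_dads_transform,
    ftir_kinetic_decomposition,
    global_fit_sequential,
    make_isolog_grid,
    svd_truncate,
)

SPECTRO_LIFETIMES = (173e-9, 6e-3, 1.2)


class TestIsologGrid:
    @pytest.mark.parametrize(
        "t0, t1, ppd, expected",
        [
            (10e-9, 100.0, 10, 101),
            (1.0, 10.0, 1, 2),
            (1.0, 100.0, 2, 5),
        ],
    )
    def test_point_counts(self, t0, t1, ppd, expected):
        grid = make_isolog_grid(t0, t1, ppd)
        assert grid.size == expected
        assert grid[0] == t0 and grid[-1] == t1

    def test_geometric_construction(self):
        grid = make_isolog_grid(1.0, 100.0, 2)
        assert np.allclose(grid, [1.0, 10**0.5, 10.0, 10**1.5, 100.0])

    def test_rejects_non_positive_times(self):
        with pytest.raises(ValueError):
            make_isolog_grid(0.0, 1.0, 10)


class TestBateman:
    def test_single_component_is_pure_exponential(self):
        t = np.linspace(0.0, 5.0, 50)
        c = bateman_concentrations([2.0], t)
        assert np.allclose(c[0], np.exp(-t / 2.0))

    def test_two_component_closed_form_against_ode(self):
        """c2 for k1=2, k2=1 equals 2(e^-t - e^-2t); c2(ln 2) = 0.5."""
        k1, k2 = 2.0, 1.0
        t = np.linspace(0.0, 6.0, 400)
        c = bateman_concentrations([1 / k1, 1 / k2], t)
        sol = solve_ivp(
            lambda _, y: [-k1 * y[0], k1 * y[0] - k2 * y[1]],
            (0, 6.0), [1.0, 0.0], t_eval=t, rtol=1e-11, atol=1e-13,
        )
        assert np.max(np.abs(c - sol.y)) < 1e-8
        assert bateman_concentrations([0.5, 1.0], [np.log(2.0)])[1, 0] == pytest.approx(0.5)

    def test_chain_probabilities_bounded(self):
        t = np.geomspace(1e-9, 100.0, 200)
        c = bateman_concentrations(SPECTRO_LIFETIMES, t)
        assert np.all(c >= -1e-12)
        assert np.all(c.sum(axis=0) <= 1.0 + 1e-12)

    def test_degenerate_lifetimes_are_jittered(self):
        c = bateman_concentrations([1.0, 1.0], np.linspace(0.0, 3.0, 30))
        assert np.all(np.isfinite(c))
        # confluent limit: c2(t) = t e^-t; jittered form must approximate it
        t = np.linspace(0.0, 3.0, 30)
        assert np.max(np.abs(c[1] - t * np.exp(-t))) < 1e-4

    def test_rejects_non_positive_lifetime(self):
        with pytest.raises(ValueError):
            bateman_concentrations([1.0, -2.0], [0.0, 1.0])


class TestSvdTruncate:
    def test_rank_one_synthetic(self):
        wl = np.linspace(300, 600, 40)
        t = np.geomspace(1e-3, 10, 30)
        data = TimeResolvedSpectra(wl, t, np.outer(np.exp(-((wl - 450) / 40) ** 2), np.exp(-t)))
        *_, rank = svd_truncate(data)
        assert rank == 1

    def test_two_components_with_noise(self):
        data = synth.gen_ftir_series(noise_sd=0.01, seed=11)
        *_, rank = svd_truncate(data)
        assert rank == 2

    def test_reconstruction_error_is_discarded_energy(self):
        data = synth.gen_ftir_series(noise_sd=0.02, seed=3)
        m = data.delta_a
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        for n in (1, 2, 3):
            un, sn, vtn, _ = svd_truncate(data, n)
            err = np.linalg.norm(m - (un * sn) @ vtn)
            assert err == pytest.approx(np.linalg.norm(s[n:]), rel=1e-9)

    def test_rejects_rank_beyond_matrix(self):
        data = synth.gen_ftir_series()
        with pytest.raises(ValueError, match="rank"):
            svd_truncate(data, 50)

    def test_excluded_ranges_drop_rows(self):
        data = synth.gen_ftir_series(excluded_ranges=((1180.0, 1260.0),))
        u, *_ = svd_truncate(data, 1)
        assert u.shape[0] == data.mask().sum() < data.axis_values.size


class TestGlobalFitSequential:
    def test_noiseless_round_trip(self):
        """Lifetimes within 0.1% and EADS within 1e-6 RMS of ground truth."""
        data = synth.gen_transient_absorption()
        wl, eads_true = synth.fixture_eads()
        result = global_fit_sequential(data, 3, [5e-7, 2e-3, 4.0])
        assert result.converged
        assert np.allclose(result.lifetimes, SPECTRO_LIFETIMES, rtol=1e-3)
        scale = data.metadata["ground_truth"]["excited_fraction"]
        rms = np.sqrt(np.mean((result.eads - scale * eads_true) ** 2))
        assert rms < 1e-6
        assert result.residual_rms < 1e-8

    @pytest.mark.parametrize("factor", [3.0, 1 / 3.0])
    def test_perturbed_initial_lifetimes_same_basin(self, factor):
        data = synth.gen_transient_absorption()
        tau_init = np.asarray(SPECTRO_LIFETIMES) * factor
        result = global_fit_sequential(data, 3, tau_init)
        assert np.allclose(result.lifetimes, SPECTRO_LIFETIMES, rtol=5e-3)

    def test_single_component_reduces_to_shared_exponential(self):
        wl = np.linspace(300, 600, 30)
        t = np.geomspace(1e-3, 30.0, 60)
        spec = np.exp(-(((wl - 500) / 30) ** 2))
        data = TimeResolvedSpectra(wl, t, np.outer(spec, np.exp(-t / 2.5)))
        result = global_fit_sequential(data, 1, [1.0])
        assert result.lifetimes[0] == pytest.approx(2.5, rel=1e-6)
        assert np.allclose(result.eads[:, 0], spec, atol=1e-9)

    def test_last_eads_matches_long_time_spectrum(self):
        """EADS of the slowest component is the late-time difference spectrum."""
        data = synth.gen_transient_absorption()
        result = global_fit_sequential(data, 3, [5e-7, 2e-3, 4.0])
        t_late = np.array([5.0 * max(SPECTRO_LIFETIMES)])
        c_late = bateman_concentrations(result.lifetimes, t_late)
        # at t = 5 tau_max only the last compartment survives
        recon = result.reconstruct(t_late)[:, 0]
        assert np.allclose(recon, result.eads[:, -1] * c_late[-1, 0], atol=1e-12)

    def test_noisy_lifetime_recovery_over_seeds(self):
        """1% noise, 20 seeds: every lifetime within 5% relative error."""
        errors = []
        wl = np.arange(310.0, 651.0, 8.0)
        for seed in range(20):
            data = synth.gen_transient_absorption(
                wavelengths=wl, noise_sd=0.0025, seed=seed
            )
            result = global_fit_sequential(data, 3, [5e-7, 2e-3, 4.0])
            errors.append(np.abs(result.lifetimes - SPECTRO_LIFETIMES) / SPECTRO_LIFETIMES)
        assert np.median(np.max(errors, axis=1)) <= 0.05

    def test_warns_when_components_exceed_rank(self):
        data = synth.gen_ftir_series()  # rank 2
        with pytest.warns(UserWarning, match="rank"):
            globalfit.SequentialSpectralModel(data, 3)


class TestEadsDadsTransform:
    def test_single_component_identity(self):
        spec = np.random.default_rng(0).normal(size=(20, 1))
        out = eads_dads_transform(spec, [2.0], "eads->dads")
        assert np.allclose(out, spec)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(1)
        eads = rng.normal(size=(40, 3))
        dads = eads_dads_transform(eads, SPECTRO_LIFETIMES, "eads->dads")
        back = eads_dads_transform(dads, SPECTRO_LIFETIMES, "dads->eads")
        assert np.max(np.abs(back - eads)) <= 1e-12 * np.max(np.abs(eads))

    def test_both_representations_reconstruct_data(self):
        """EADS x Bateman == DADS x pure exponentials, elementwise."""
        rng = np.random.default_rng(2)
        taus = np.array([0.3, 3.0])
        eads = rng.normal(size=(25, 2))
        t = np.linspace(0.0, 10.0, 80)
        from_eads = eads @ bateman_concentrations(taus, t)
        dads = eads_dads_transform(eads, taus, "eads->dads")
        from_dads = dads @ np.exp(-np.outer(1.0 / taus, t))
        assert np.max(np.abs(from_eads - from_dads)) < 1e-12
        # 2-component relation: DADS1 = EADS1 - k1/(k1-k2) * EADS2 ... via A
        a = bateman_coefficients(taus)
        k1, k2 = 1.0 / taus
        assert a[1, 0] == pytest.approx(-k1 / (k1 - k2))

    def test_component_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="count"):
            eads_dads_transform(np.zeros((10, 2)), [1.0], "eads->dads")


class TestFtirDecomposition:
    def test_two_component_round_trip(self):
        data = synth.gen_ftir_series()
        spectra, taus, _ = ftir_kinetic_decomposition(data, 2)
        gt = data.metadata["ground_truth"]
        assert taus[0] == pytest.approx(gt["tau_fast_s"], rel=0.01)
        assert taus[1] == pytest.approx(gt["tau_slow_s"], rel=0.01)
        for col, truth in ((0, gt["fast_spectrum"]), (1, gt["slow_spectrum"])):
            cos = np.dot(spectra[:, col], truth) / (
                np.linalg.norm(spectra[:, col]) * np.linalg.norm(truth)
            )
            assert abs(cos) > 0.999

    def test_rank_one_input_second_amplitude_vanishes(self):
        wn = np.arange(1000.0, 1801.0, 4.0)
        t = make_isolog_grid(1e-4, 100.0, 10)
        band = np.exp(-0.5 * ((wn - 1550) / 15.0) ** 2)
        data = TimeResolvedSpectra(wn, t, np.outer(band, np.exp(-t / 0.3)), axis_kind="wavenumber")
        spectra, taus, _ = ftir_kinetic_decomposition(data, 2)
        norms = np.linalg.norm(spectra, axis=0)
        assert norms.min() <= 1e-6 * norms.max()

    def test_agrees_with_sequential_global_fit(self):
        """Exponents are representation-independent: both routes within 1%."""
        data = synth.gen_ftir_series()
        _, taus, _ = ftir_kinetic_decomposition(data, 2)
        seq = global_fit_sequential(data, 2, [1e-3, 5.0])
        assert np.allclose(taus, seq.lifetimes, rtol=0.01)
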