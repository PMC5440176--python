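import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sps
from scipy.integrate import solve_ivp

from hopfnet import (
    ConnectomeMatrix,
    DivergenceError,
    HopfParams,
    StructuralError,
    ValidationError,
    hopf_drift,
    load_result,
    save_result,
    simulate_multifrequency,
    simulate_network,
)


class TestDrift:
    def test_uniform_state_has_zero_coupling(self, small_connectome):
        """Diffusive coupling vanishes identically on spatially uniform states."""
        n = small_connectome.n
        params = HopfParams(f_f=5.0, G=0.8, a=0.3)
        x, y = np.full(n, 0.37), np.full(n, -0.21)
        dx0, dy0 = hopf_drift(x, y, replace(params, G=0.0), small_connectome)
        dx1, dy1 = hopf_drift(x, y, params, small_connectome)
        np.testing.assert_array_equal(dx0, dx1)
        np.testing.assert_array_equal(dy0, dy1)

    def test_hand_evaluated_rates(self):
        """Uncoupled node at (1, 0), a=0, omega=2*pi gives (-1, 2*pi)."""
        C = ConnectomeMatrix(np.zeros((1, 1)))
        params = HopfParams(f_f=1.0, G=0.0, a=0.0)
        dx, dy = hopf_drift([1.0], [0.0], params, C)
        assert dx[0] == pytest.approx(-1.0, abs=1e-12)
        assert dy[0] == pytest.approx(2 * np.pi, abs=1e-12)

    def test_origin_is_fixed_point(self, small_connectome):
        n = small_connectome.n
        dx, dy = hopf_drift(np.zeros(n), np.zeros(n),
                            HopfParams(f_f=10.0), small_connectome)
        assert not dx.any() and not dy.any()

    def test_shape_mismatch_rejected(self, small_connectome):
        with pytest.raises(StructuralError):
            hopf_drift([1.0, 0.0], [0.0, 0.0], HopfParams(f_f=1.0),
                       small_connectome)


class TestSimulate:
    def test_limit_cycle_radius(self, small_connectome):
        """Noise-free uncoupled nodes with a=1 settle on |z| = sqrt(a) = 1."""
        n = small_connectome.n
        params = HopfParams(f_f=12.0, G=0.0, a=1.0, beta=0.0,
                            duration=20.0, burn_in=10.0, seed=0)
        res = simulate_network(
            small_connectome, params,
            initial_state=(np.full(n, 0.5), np.zeros(n)),
        )
        radius = np.abs(res.signal + 1j * res.signal_y)
        np.testing.assert_allclose(radius, 1.0, atol=1e-3)

    def test_origin_fixed_point(self, small_connectome):
        n = small_connectome.n
        params = HopfParams(f_f=12.0, G=0.0, a=0.0, beta=0.0,
                            duration=5.0, burn_in=1.0, seed=0)
        res = simulate_network(small_connectome, params,
                               initial_state=(np.zeros(n), np.zeros(n)))
        assert not res.signal.any()

    def test_seed_determinism(self, small_connectome, fast_params):
        a = simulate_network(small_connectome, fast_params)
        b = simulate_network(small_connectome, fast_params)
        assert a.signal.tobytes() == b.signal.tobytes()
        c = simulate_network(small_connectome, replace(fast_params, seed=99))
        assert a.signal.tobytes() != c.signal.tobytes()

    def test_output_length_contract(self, small_connectome):
        params = HopfParams(f_f=8.0, duration=7.3, burn_in=1.1,
                            output_rate=125.0, seed=2)
        res = simulate_network(small_connectome, params)
        assert res.n_samples == int(np.floor((7.3 - 1.1) * 125.0))
        assert np.all(np.isfinite(res.signal))

    def test_spectral_peak_at_fundamental(self, small_connectome):
        """Noise-driven subcritical node: Lorentzian spectrum centred at f_f."""
        params = HopfParams(f_f=12.0, G=0.0, a=-0.5, beta=0.02,
                            duration=120.0, burn_in=10.0, seed=5)
        res = simulate_network(small_connectome, params)
        f, pxx = sps.welch(res.signal, fs=res.sampling_rate, nperseg=4096)
        peak = f[pxx.mean(axis=0).argmax()]
        assert abs(peak - 12.0) <= f[1] - f[0]

    def test_uniform_noise_free_trajectory_is_g_independent(
        self, small_connectome
    ):
        """With identical initial nodes and no noise, G has no effect at all."""
        n = small_connectome.n
        init = (np.full(n, 0.4), np.full(n, -0.2))
        base = HopfParams(f_f=7.0, a=1.0, beta=0.0, duration=6.0,
                          burn_in=0.0, seed=0)
        r0 = simulate_network(small_connectome, replace(base, G=0.0), init)
        r1 = simulate_network(small_connectome, replace(base, G=0.9), init)
        assert r0.signal.tobytes() == r1.signal.tobytes()

    def test_half_step_convergence(self, small_connectome):
        """Halving dt roughly halves the noise-free global error (order 1)."""
        n = small_connectome.n
        w = small_connectome.weights
        params = HopfParams(f_f=3.0, G=0.4, a=1.0, beta=0.0,
                            duration=2.0, burn_in=0.0, output_rate=100.0,
                            seed=0)
        x0 = np.linspace(0.2, 0.8, n)
        y0 = np.linspace(-0.3, 0.3, n)
        omega = params.omega

        def rhs(_, state):
            x, y = state[:n], state[n:]
            dx, dy = hopf_drift(x, y, params, small_connectome)
            return np.r_[dx, dy]

        t_eval = params.burn_in + np.arange(
            int(params.duration * params.output_rate)
        ) / params.output_rate
        ref = solve_ivp(rhs, (0, params.duration), np.r_[x0, y0],
                        t_eval=t_eval, rtol=1e-10, atol=1e-12)
        ref_x = ref.y[:n]

        errs = []
        for dt in (1e-3, 5e-4):
            res = simulate_network(small_connectome, replace(params, dt=dt),
                                   initial_state=(x0, y0))
            errs.append(np.abs(res.signal - ref_x).max())
        assert errs[1] < errs[0]
        assert 1.3 < errs[0] / errs[1] < 3.5  # ~2 for a first-order scheme

    def test_divergence_reported_with_step(self, small_connectome):
        n = small_connectome.n
        params = HopfParams(f_f=12.0, G=0.0, beta=0.0, duration=2.0,
                            burn_in=0.0, seed=0)
        with pytest.raises(DivergenceError) as err:
            simulate_network(small_connectome, params,
                             initial_state=(np.full(n, 600.0), np.zeros(n)))
        assert err.value.step >= 0

    def test_stability_across_coupling_range(self, sc90):
        """a=0, beta=0.02: no divergence anywhere on the G grid (short runs)."""
        for G in (0.0, 0.5, 1.0):
            params = HopfParams(f_f=12.0, G=G, duration=30.0, burn_in=5.0,
                                seed=11)
            res = simulate_network(sc90, params)
            assert np.all(np.isfinite(res.signal))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            HopfParams(f_f=12.0, dt=-1.0).validate()
        with pytest.raises(ValidationError):
            HopfParams(f_f=12.0, duration=5.0, burn_in=6.0).validate()
        with pytest.raises(ValidationError):
            HopfParams(f_f=12.0, output_rate=2000.0).validate()
        with pytest.raises(ValidationError):
            HopfParams(f_f=-3.0).validate()


class TestMultifrequency:
    def test_single_layer_degenerates_to_single_model(self, small_connectome,
                                                      fast_params):
        multi = simulate_multifrequency(small_connectome, fast_params,
                                        [12.0], [fast_params.seed])
        single = simulate_network(small_connectome, fast_params)
        np.testing.assert_array_equal(multi[0].signal, single.signal)

    def test_seven_layers(self, small_connectome, fast_params):
        ffs = [4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0]
        out = simulate_multifrequency(small_connectome, fast_params, ffs,
                                      list(range(7)))
        assert [r.params.f_f for r in out] == ffs

    def test_layers_peak_at_own_frequency(self, small_connectome):
        base = HopfParams(f_f=12.0, G=0.0, a=-0.3, duration=60.0,
                          burn_in=5.0, seed=4)
        out = simulate_multifrequency(small_connectome, base, [8.0, 20.0],
                                      [4, 4])
        for res in out:
            f, pxx = sps.welch(res.signal, fs=res.sampling_rate, nperseg=2048)
            peak = f[pxx.mean(axis=0).argmax()]
            assert abs(peak - res.params.f_f) <= 2 * (f[1] - f[0])

    def test_duplicate_frequencies_rejected(self, small_connectome,
                                            fast_params):
        with pytest.raises(ValidationError):
            simulate_multifrequency(small_connectome, fast_params,
                                    [12.0, 12.0], [1, 2])

    def test_mismatched_seed_list_rejected(self, small_connectome,
                                           fast_params):
        with pytest.raises(ValidationError):
            simulate_multifrequency(small_connectome, fast_params,
                                    [4.0, 8.0], [1])


class TestIO:
    def test_save_load_roundtrip(self, tmp_path, small_connectome,
                                 fast_params):
        res = simulate_network(small_connectome, fast_params)
        save_result(res, tmp_path / "run")
        back = load_result(tmp_path / "run")
        np.testing.assert_array_equal(back.signal, res.signal)
        assert back.sampling_rate == res.sampling_rate
        assert back.params.f_f == res.params.f_f
        assert back.connectome_id == res.connectome_id
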