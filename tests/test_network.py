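"""Network construction, LFP spectral analysis and synchrony metrics.

Structural and spectral checks use small networks or constructed signals;
the full 220-cell reproductions live in the acceptance suite."""

import numpy as np
import pytest

from pvnet.network import (
    LFP_MV_PER_NA,
    NetworkResult,
    NetworkSpec,
    build_network,
    compute_lfp,
    measure_psp,
    run_network,
    synchrony_metrics,
)
from pvnet.synthdata import generate_poisson_trains


def _small_spec(**kw):
    base = dict(n_pc=20, n_pv=5, duration_ms=500.0, settle_ms=100.0)
    base.update(kw)
    return NetworkSpec(**base)


class TestBuildNetwork:
    def test_zero_probability_no_edges(self):
        spec = _small_spec(p_pc_pc=0.0, p_pv_pc=0.0, p_pv_pv_chem=0.0,
                           p_pv_pv_gap=0.0, p_pc_pv=0.0)
        r = build_network(spec, seed=0)
        for m in (r.w_pc_pc, r.w_pv_pc, r.w_pc_pv, r.w_pv_pv, r.g_gap):
            assert np.count_nonzero(m) == 0

    def test_full_probability_complete_graphs(self):
        spec = _small_spec(p_pc_pc=1.0, p_pv_pc=1.0, p_pv_pv_chem=1.0,
                           p_pv_pv_gap=1.0, p_pc_pv=1.0)
        r = build_network(spec, seed=0)
        n_pc, n_pv = spec.n_pc, spec.n_pv
        assert np.count_nonzero(r.w_pc_pc) == n_pc * (n_pc - 1)
        assert np.count_nonzero(r.w_pv_pv) == n_pv * (n_pv - 1)
        assert np.count_nonzero(r.g_gap) == n_pv * (n_pv - 1)  # symmetric

    def test_no_self_connections(self):
        r = build_network(_small_spec(), seed=3)
        assert np.all(np.diag(r.w_pc_pc) == 0)
        assert np.all(np.diag(r.w_pv_pv) == 0)

    def test_gap_matrix_symmetric(self):
        r = build_network(NetworkSpec(), seed=1)
        np.testing.assert_array_equal(r.g_gap, r.g_gap.T)

    def test_realized_fraction_matches_binomial(self):
        """Mean realized PV->PC fraction over seeds is within 3 SE of 0.36."""
        spec = NetworkSpec()
        n_trials = 30 * spec.n_pc * spec.n_pv
        fracs = []
        for s in range(30):
            r = build_network(spec, seed=s)
            fracs.append(np.count_nonzero(r.w_pv_pc) / (spec.n_pc * spec.n_pv))
        se = np.sqrt(0.36 * 0.64 / n_trials)
        assert abs(np.mean(fracs) - 0.36) < 3 * se

    def test_seeded_determinism(self):
        a = build_network(NetworkSpec(), seed=5)
        b = build_network(NetworkSpec(), seed=5)
        np.testing.assert_array_equal(a.w_pc_pc, b.w_pc_pc)
        np.testing.assert_array_equal(a.pc_bias, b.pc_bias)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(p_pc_pc=1.5)


class TestRunNetwork:
    def test_decoupled_network_matches_isolated_cells(self):
        """With all connection probabilities zero, each cell fires at its
        isolated bias-current rate."""
        from pvnet.cells import make_pc_cell, simulate
        from pvnet.protocols import detect_spikes

        spec = _small_spec(p_pc_pc=0.0, p_pv_pc=0.0, p_pv_pv_chem=0.0,
                           p_pv_pv_gap=0.0, p_pc_pv=0.0)
        real = build_network(spec, seed=2)
        res = run_network(spec, 0.0, seed=2, realization=real)
        # compare three PCs against single-cell runs at the same bias
        model = make_pc_cell()
        for i in (0, 7, 13):
            tr = simulate(model, spec.duration_ms, i_inj_pA=float(real.pc_bias[i]),
                          v0=-60.0, settle_ms=spec.settle_ms)
            iso = len(detect_spikes(tr).times_ms)
            assert abs(len(res.pc_spikes[i]) - iso) <= 1

    def test_run_is_deterministic(self):
        spec = _small_spec()
        a = run_network(spec, 0.0, seed=4)
        b = run_network(spec, 0.0, seed=4)
        for x, y in zip(a.pc_spikes, b.pc_spikes):
            np.testing.assert_array_equal(x, y)
        np.testing.assert_array_equal(a.lfp_current_nA, b.lfp_current_nA)

    def test_raster_covers_all_cells(self):
        spec = _small_spec()
        res = run_network(spec, 0.0, seed=1)
        df = res.raster()
        assert df.cell_id.max() < spec.n_pc + spec.n_pv


class TestLFP:
    def _silent_result(self, n=40001, dt=0.025):
        return NetworkResult(pc_spikes=[], pv_spikes=[],
                             lfp_current_nA=np.zeros(n),
                             duration_ms=(n - 1) * dt, dt_ms=dt,
                             delta_shift=0.0, seed=0)

    def test_silent_network_gamma_at_noise_floor(self):
        lfp = compute_lfp(self._silent_result())
        assert lfp.gamma_power < 1e-20

    def test_sinusoid_peak_and_quadratic_power(self):
        """A pure 40 Hz current gives a 40 Hz spectral peak and gamma
        power scaling with amplitude squared."""
        dt = 0.025
        t = np.arange(40001) * dt
        gammas = []
        for amp in (1.0, 2.0):
            cur = amp * np.sin(2 * np.pi * 40.0 * t / 1000.0)
            res = NetworkResult(pc_spikes=[], pv_spikes=[], lfp_current_nA=cur,
                                duration_ms=t[-1], dt_ms=dt, delta_shift=0.0,
                                seed=0)
            lfp = compute_lfp(res)
            peak_f = lfp.freqs_hz[np.argmax(lfp.psd_mV2_per_hz)]
            assert peak_f == pytest.approx(40.0, abs=2.0)
            gammas.append(lfp.gamma_power)
        assert gammas[1] / gammas[0] == pytest.approx(4.0, rel=0.05)

    def test_sinusoid_power_parseval(self):
        """Integrated PSD of a sinusoid at the band-pass center (~16 Hz,
        where the filter gain is 1) approximates its mean square
        (amplitude^2/2 after volume-conduction scaling)."""
        dt = 0.025
        t = np.arange(80001) * dt
        amp_nA = 3.0
        f0 = np.sqrt(5.0 * 50.0)  # geometric band center
        cur = amp_nA * np.sin(2 * np.pi * f0 * t / 1000.0)
        res = NetworkResult(pc_spikes=[], pv_spikes=[], lfp_current_nA=cur,
                            duration_ms=t[-1], dt_ms=dt, delta_shift=0.0, seed=0)
        lfp = compute_lfp(res)
        total = np.trapezoid(lfp.psd_mV2_per_hz, lfp.freqs_hz)
        expected = (amp_nA * LFP_MV_PER_NA) ** 2 / 2.0
        assert total == pytest.approx(expected, rel=0.1)

    def test_short_run_rejected(self):
        res = self._silent_result(n=4001)  # 100 ms < 2 periods of 5 Hz
        with pytest.raises(ValueError):
            compute_lfp(res)


class TestSynchrony:
    def test_duplicated_train_perfectly_correlated(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 1000.0, 40))
        out = synchrony_metrics([t, t.copy()], 1000.0)
        assert out["mean_correlation"] == pytest.approx(1.0)

    def test_independent_poisson_decorrelated(self):
        trains = generate_poisson_trains(30.0, 2000.0, 40, seed=1)
        out = synchrony_metrics(trains, 2000.0)
        assert abs(out["mean_correlation"]) < 0.05

    def test_needs_two_trains(self):
        with pytest.raises(ValueError):
            synchrony_metrics([np.array([1.0])], 100.0)


class TestPSPConstraint:
    @pytest.mark.parametrize("pre,post,w_attr", [
        ("pc", "pc", "w_pc_pc_nS"),
        ("pc", "pv", "w_pc_pv_nS"),
        ("pv", "pc", "w_pv_pc_nS"),
    ])
    def test_default_weights_give_submv_psps(self, pre, post, w_attr):
        """The amplitude-constrained projections (PC->PC, PC->PV, PV->PC)
        give sub-mV somatic PSPs at the calibrated weights.  PV->PV is
        calibrated for recurrent-synchrony strength, not amplitude."""
        spec = NetworkSpec()
        psp = measure_psp(pre, post, getattr(spec, w_attr), spec=spec)
        assert psp < 1.0
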