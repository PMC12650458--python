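import numpy as np
import pytest
from scipy import stats

from neurofuse.granger import (
    DegenerateFitError,
    cross_modal_gc,
    eeg_gc_matrix,
    fit_ar,
    gc_pair,
    select_order,
)
from neurofuse.preprocess import Recording

from .oracles import ar_ols_coefficients, brute_force_gc


def _ar2(rng, n, coeffs=(0.5, -0.3)):
    x = np.zeros(n + 200)
    e = rng.standard_normal(n + 200)
    for t in range(2, n + 200):
        x[t] = coeffs[0] * x[t - 1] + coeffs[1] * x[t - 2] + e[t]
    return x[200:]


class TestFitAr:
    def test_white_noise_coefficient_near_zero(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        fit = fit_ar(x, [x], order=1)
        assert abs(fit.coefficients[0, 0]) < 3 / np.sqrt(n)
        assert fit.n_effective == n - 1

    def test_deterministic_recursion_degenerate(self):
        x = np.empty(500)
        x[0] = 1.0
        for t in range(1, 500):
            x[t] = 0.9 * x[t - 1]
        with pytest.raises(DegenerateFitError):
            fit_ar(x, [x], order=1)

    def test_ar2_coefficients_recovered(self, rng):
        x = _ar2(rng, 5000)
        fit = fit_ar(x, [x], order=2)
        assert np.allclose(fit.coefficients[0], [0.5, -0.3], atol=0.05)
        # matches an independent normal-equations solve
        assert np.allclose(
            fit.coefficients[0], ar_ols_coefficients(x, 2), atol=1e-8
        )

    def test_insufficient_samples_raise(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            fit_ar(rng.standard_normal(12), [rng.standard_normal(12)], order=5)


class TestSelectOrder:
    def test_white_noise_prefers_small_order(self):
        small = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            x = rng.standard_normal(2000)
            y = rng.standard_normal(2000)
            if select_order(x, y, max_order=10) <= 2:
                small += 1
        assert small >= 90

    def test_var2_order_recovered(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            n = 5000
            x = np.zeros(n + 100)
            y = np.zeros(n + 100)
            ex = rng.standard_normal(n + 100)
            ey = rng.standard_normal(n + 100)
            for t in range(2, n + 100):
                x[t] = 0.4 * x[t - 1] - 0.35 * x[t - 2] + 0.4 * y[t - 2] + ex[t]
                y[t] = 0.5 * y[t - 1] - 0.3 * y[t - 2] + ey[t]
            if select_order(x[100:], y[100:], max_order=6) == 2:
                hits += 1
        assert hits >= 80

    def test_single_candidate(self, rng):
        x = rng.standard_normal(500)
        assert select_order(x, rng.standard_normal(500), max_order=1) == 1


class TestGcPair:
    def test_null_pair_f_small(self, rng):
        n, order = 5000, 5
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        f = gc_pair(x, y, order).f
        assert 0.0 <= f < 3 * order / n * 5

    def test_directed_coupling_detected(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = rng.standard_normal()
        y[1:] = 0.8 * x[:-1] + rng.standard_normal(n - 1)
        assert gc_pair(y, x, order=2).f > 0.1  # x -> y strong
        assert gc_pair(x, y, order=2).f < 0.02  # y -> x null

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        base_xy = gc_pair(x, y, 3).f
        base_yx = gc_pair(y, x, 3).f
        assert abs(gc_pair(7.3 * x, 0.2 * y, 3).f - base_xy) < 1e-10
        assert abs(gc_pair(0.2 * y, 7.3 * x, 3).f - base_yx) < 1e-10

    def test_matches_brute_force_oracle(self):
        for rep in range(20):
            rng = np.random.default_rng(rep)
            order = int(rng.integers(1, 4))
            x = rng.standard_normal(400)
            y = rng.standard_normal(400)
            assert abs(gc_pair(x, y, order).f - brute_force_gc(x, y, order)) < 1e-8

    def test_matches_statsmodels_likelihood_ratio(self, rng):
        """n_eff * F agrees with statsmodels' Granger LR statistic."""
        from statsmodels.tsa.stattools import grangercausalitytests

        n, order = 4000, 2
        x = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = rng.standard_normal()
        y[1:] = 0.5 * x[:-1] + rng.standard_normal(n - 1)
        stat = (n - order) * gc_pair(y, x, order).f
        res = grangercausalitytests(
            np.column_stack([y, x]), maxlag=[order], verbose=False
        )
        lr = res[order][0]["lrtest"][0]
        assert stat == pytest.approx(lr, rel=1e-4)

    def test_nestedness_nonnegative(self, rng):
        for _ in range(50):
            n = int(rng.integers(100, 400))
            order = int(rng.integers(1, 5))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert gc_pair(x, y, order).f >= 0.0

    def test_null_statistic_matches_chi2(self):
        """n_eff * F under independence follows chi-square(order)."""
        order, n, reps = 3, 2000, 300
        fs = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng(50_000 + rep)
            fs[rep] = gc_pair(
                rng.standard_normal(n), rng.standard_normal(n), order
            ).f
        stat = stats.kstest((n - order) * fs, stats.chi2(order).cdf).statistic
        assert stat < 0.1

    def test_detection_monotone_in_coupling(self):
        """Population F grows with the coupling coefficient magnitude."""
        means = []
        for ci, c in enumerate((0.0, 0.2, 0.4, 0.8)):
            vals = []
            for rep in range(10):
                rng = np.random.default_rng(9000 + 100 * ci + rep)
                n = 20000
                x = rng.standard_normal(n)
                y = np.empty(n)
                y[0] = rng.standard_normal()
                y[1:] = c * x[:-1] + rng.standard_normal(n - 1)
                vals.append(gc_pair(y, x, order=1).f)
            means.append(np.mean(vals))
        assert all(b >= a - 1e-4 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.1


class TestEegGcMatrix:
    def test_white_noise_entries_near_null(self, rng):
        order, n = 2, 3000
        rec = Recording(rng.standard_normal((3, n)), 200.0)
        mats = eeg_gc_matrix({"alpha": rec}, order_policy=order)
        v = mats["alpha"].values
        thresh = stats.chi2(order).ppf(0.95) / (n - order)
        off = v[~np.eye(3, dtype=bool)]
        assert (off < thresh).mean() >= 0.85

    def test_single_coupling_argmax(self):
        from neurofuse.synthetic import CouplingSpec, simulate_var

        a = np.zeros((1, 3, 3))
        np.fill_diagonal(a[0], 0.5)
        a[0][1, 0] = 0.4  # channel 0 drives channel 1
        spec = CouplingSpec(1, a, np.eye(3))
        x = simulate_var(spec, 5000, seed=3)
        mats = eeg_gc_matrix({"beta": Recording(x, 200.0)}, order_policy=2)
        v = mats["beta"].values.copy()
        np.fill_diagonal(v, -np.inf)
        assert np.unravel_index(v.argmax(), v.shape) == (0, 1)

    def test_diagonal_zero_and_nonnegative(self, rng):
        rec = Recording(rng.standard_normal((4, 1000)), 200.0)
        mats = eeg_gc_matrix({"theta": rec}, order_policy=3)
        v = mats["theta"].values
        assert np.all(np.diag(v) == 0)
        assert np.all(v >= 0)

    def test_fast_path_matches_gc_pair(self, rng):
        data = rng.standard_normal((4, 600))
        rec = Recording(data, 200.0)
        mats = eeg_gc_matrix({"gamma": rec}, order_policy=3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                ref = gc_pair(data[j], data[i], 3).f
                assert abs(mats["gamma"].values[i, j] - ref) < 1e-8


class TestCrossModalGc:
    def test_independent_signals_near_null(self, rng):
        order, n = 2, 3000
        eeg = Recording(rng.standard_normal((3, n)), 200.0)
        fnirs = Recording(rng.standard_normal((2, n)), 200.0, modality="hbo2")
        f2e, e2f = cross_modal_gc(eeg, fnirs, order_policy=order)
        thresh = stats.chi2(order).ppf(0.95) / (n - order)
        pooled = np.concatenate([f2e.values.ravel(), e2f.values.ravel()])
        assert (pooled < thresh).mean() >= 0.85

    def test_rate_mismatch_raises(self, rng):
        eeg = Recording(rng.standard_normal((2, 400)), 200.0)
        fnirs = Recording(rng.standard_normal((2, 400)), 11.0, modality="hbo2")
        with pytest.raises(ValueError, match="rate mismatch"):
            cross_modal_gc(eeg, fnirs)

    def test_zero_variance_channel_degenerate(self, rng):
        eeg = Recording(rng.standard_normal((2, 800)), 200.0)
        flat = np.vstack([np.zeros(800), rng.standard_normal(800)])
        fnirs = Recording(flat, 200.0, modality="hbo2")
        with pytest.raises(DegenerateFitError):
            cross_modal_gc(eeg, fnirs, order_policy=2)

    def test_shapes_and_directions(self, rng):
        eeg = Recording(rng.standard_normal((3, 900)), 200.0)
        fnirs = Recording(rng.standard_normal((2, 900)), 200.0, modality="hbo2")
        f2e, e2f = cross_modal_gc(eeg, fnirs, order_policy=2)
        assert f2e.values.shape == (2, 3) and f2e.direction == "fnirs->eeg"
        assert e2f.values.shape == (3, 2) and e2f.direction == "eeg->fnirs"

    def test_nvc_coupling_raises_eeg_to_fnirs_gc(self):
        """Hemodynamically coupled pairs show higher EEG->fNIRS GC than
        uncoupled pairs (paired comparison across replicates)."""
        from neurofuse.preprocess import resample
        from neurofuse.synthetic import _band_power_envelope, simulate_fnirs_from_eeg

        diffs = []
        for rep in range(30):
            rng = np.random.default_rng(777 + rep)
            eeg = rng.standard_normal((4, 44000))  # 220 s at 200 Hz
            hbo2, _ = simulate_fnirs_from_eeg(
                eeg, 200.0, nvc_gain=10.0, fs_out=11.0, seed=rep,
                n_fnirs_channels=2, noise_sd=0.3,
            )
            env = _band_power_envelope(eeg, 200.0)
            env -= env.mean(axis=1, keepdims=True)
            env11 = resample(Recording(env, 200.0), 11.0).data
            n = min(env11.shape[1], hbo2.shape[1])
            env_rec = Recording(env11[:, :n], 11.0, modality="eeg")
            fn_rec = Recording(hbo2[:, :n], 11.0, modality="hbo2")
            _, e2f = cross_modal_gc(
                env_rec, fn_rec, order_policy=25, directions=("eeg->fnirs",)
            )
            v = e2f.values  # [4 env channels x 2 optical channels]
            coupled = [v[z, k] for k in range(2) for z in range(4) if z % 2 == k]
            uncoupled = [v[z, k] for k in range(2) for z in range(4) if z % 2 != k]
            diffs.append(np.mean(coupled) - np.mean(uncoupled))
        assert stats.wilcoxon(diffs, alternative="greater").pvalue < 0.01
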