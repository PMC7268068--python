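"""Pattern basis construction and trial/time-series simulation."""

import numpy as np
import pytest

from fearpattern import (
    DesignParams,
    SynthParams,
    assign_reinforcement,
    build_design_matrix,
    estimate_trial_betas,
    generate_design,
    make_pattern_basis,
    simulate_betas,
    simulate_timeseries,
)
from fearpattern.design import ALL_STIMULI, StimulusId
from fearpattern.mvpa import decode_condition, make_running_index_folds, zscore_across_trials


class TestPatternBasis:
    def test_contrast_norms_equal_amplitudes(self):
        p = SynthParams(n_voxels=80, stimulus_amp=1.3, threat_amp=0.7, complex_attenuation=0.5, seed=2)
        basis = make_pattern_basis(p)
        for (ctx, cx), v in basis.stimulus_contrasts.items():
            expected = 1.3 * (0.5 if cx == "complex" else 1.0)
            assert np.linalg.norm(v) == pytest.approx(expected)
        for cx, v in basis.threat_contrasts.items():
            assert np.linalg.norm(v) == pytest.approx(0.7)

    def test_pair_separation_equal_when_threat_absent(self):
        # with threat_amp = 0 the CS pair is separated by exactly the same
        # norm as the NS pair, by construction
        p = SynthParams(n_voxels=50, threat_amp=0.0, complex_attenuation=1.0, seed=1)
        basis = make_pattern_basis(p)
        dists = {}
        for ctx in ("reinforcement", "nonreinforcement"):
            for cx in ("simple", "complex"):
                d = basis.mean_pattern(StimulusId("S2", ctx, cx)) - basis.mean_pattern(
                    StimulusId("S1", ctx, cx)
                )
                dists[(ctx, cx)] = np.linalg.norm(d)
        vals = list(dists.values())
        assert np.allclose(vals, vals[0])

    def test_orthogonal_mode_components_orthogonal(self):
        p = SynthParams(n_voxels=40, basis_mode="orthogonal", seed=7)
        basis = make_pattern_basis(p)
        comps = list(basis.stimulus_contrasts.values()) + list(basis.threat_contrasts.values())
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                assert abs(comps[i] @ comps[j]) < 1e-10

    def test_orthogonal_mode_needs_enough_voxels(self):
        with pytest.raises(ValueError, match="orthogonal"):
            make_pattern_basis(SynthParams(n_voxels=3, basis_mode="orthogonal"))

    def test_gaussian_components_nearly_uncorrelated(self):
        # average |correlation| between two random components ~ sqrt(2/(pi n))
        n = 500
        corrs = []
        for seed in range(40):
            basis = make_pattern_basis(SynthParams(n_voxels=n, seed=seed))
            a = basis.stimulus_contrasts[("reinforcement", "simple")]
            b = basis.stimulus_contrasts[("nonreinforcement", "simple")]
            corrs.append(abs(np.corrcoef(a, b)[0, 1]))
        assert np.mean(corrs) < 3.0 / np.sqrt(n)

    def test_threat_support_restricts_and_keeps_norm(self):
        n = 60
        support = np.zeros(n, bool)
        support[:10] = True
        basis = make_pattern_basis(SynthParams(n_voxels=n, threat_amp=2.0, seed=3), threat_support=support)
        for v in basis.threat_contrasts.values():
            assert np.all(v[~support] == 0)
            assert np.linalg.norm(v) == pytest.approx(2.0)

    def test_deterministic_in_seed(self):
        a = make_pattern_basis(SynthParams(n_voxels=30, seed=5))
        b = make_pattern_basis(SynthParams(n_voxels=30, seed=5))
        assert np.array_equal(a.mean_pattern(ALL_STIMULI[0]), b.mean_pattern(ALL_STIMULI[0]))


class TestSimulateBetas:
    def test_noiseless_rows_equal_condition_means(self, small_design):
        p = SynthParams(n_voxels=20, noise_sd=0.0, seed=1)
        basis = make_pattern_basis(p)
        b = simulate_betas(small_design, basis, p, rng=0)
        for row, t in zip(b.data, small_design.trials):
            assert np.allclose(row, basis.mean_pattern(t.stimulus))

    def test_condition_mean_standard_error(self, default_design):
        # 24 trials per condition, unit noise: per-voxel sample-mean error ~ 1/sqrt(24)
        p = SynthParams(n_voxels=200, noise_sd=1.0, seed=2)
        basis = make_pattern_basis(p)
        b = simulate_betas(default_design, basis, p, rng=3)
        stim = ALL_STIMULI[0]
        rows = [i for i, t in enumerate(default_design.trials) if t.stimulus == stim]
        err = b.data[rows].mean(axis=0) - basis.mean_pattern(stim)
        rms = np.sqrt(np.mean(err**2))
        se = 1.0 / np.sqrt(len(rows))
        assert 0.7 * se < rms < 1.3 * se

    def test_strong_threat_signal_perfectly_decodable(self, default_design):
        p = SynthParams(n_voxels=30, threat_amp=50.0, noise_sd=0.5, seed=4)
        basis = make_pattern_basis(p)
        b = simulate_betas(default_design, basis, p, rng=5)
        info = b.trial_info
        sel = np.flatnonzero(
            (info.reinforced == 0) & (info.context == "reinforcement") & (info.complexity == "simple")
        )
        X = zscore_across_trials(b.data[sel])
        labels = info.trial_type.to_numpy()[sel]
        acc = decode_condition(X, labels, make_running_index_folds(labels))
        assert acc == 1.0

    def test_accuracy_monotone_in_stimulus_amplitude(self, default_design):
        # decoding accuracy of the NS pair is non-decreasing along an amplitude ladder
        accs = []
        for amp in (0.2, 0.8, 2.5):
            vals = []
            for seed in range(6):
                p = SynthParams(n_voxels=30, stimulus_amp=amp, threat_amp=0.0, seed=seed)
                basis = make_pattern_basis(p)
                b = simulate_betas(default_design, basis, p, rng=100 + seed)
                info = b.trial_info
                sel = np.flatnonzero(
                    (info.context == "nonreinforcement") & (info.complexity == "simple")
                )
                X = zscore_across_trials(b.data[sel])
                labels = info.trial_type.to_numpy()[sel]
                vals.append(decode_condition(X, labels, make_running_index_folds(labels)))
            accs.append(np.mean(vals))
        assert accs[0] <= accs[1] <= accs[2]


class TestSimulateTimeseries:
    def test_single_trial_traces_hrf(self):
        # one trial, no noise: the voxel time course is proportional to the
        # HRF sampled at the scan grid
        from fearpattern.glm import canonical_hrf

        p = DesignParams(n_blocks=2, trials_per_block=4, reinforcement_rate=0.0, seed=0)
        d = generate_design(p)
        d.trials = d.trials[:1]
        sp = SynthParams(n_voxels=3, noise_sd=0.0, seed=1)
        basis = make_pattern_basis(sp)
        tr = 2.5
        sim = simulate_timeseries(d, basis, sp, tr=tr, rng=0)
        hrf = canonical_hrf(tr / 16)
        onset = d.trials[0].onset
        expected = np.zeros(len(sim.scan_times))
        for i, t in enumerate(sim.scan_times):
            lag = t - onset
            idx = int(round(lag / hrf.dt))
            if 0 <= idx < len(hrf.values):
                expected[i] = hrf.values[idx]
        amp = sim.truth.data[0]
        for v in range(3):
            assert np.allclose(sim.data[:, v], expected * amp[v], atol=1e-10)

    def test_noiseless_roundtrip_recovers_amplitudes(self, small_design):
        sp = SynthParams(n_voxels=8, noise_sd=0.4, seed=2)
        basis = make_pattern_basis(sp)
        sim = simulate_timeseries(small_design, basis, sp, tr=2.5, us_amp=1.5, rng=3)
        X = build_design_matrix(small_design, 2.5)
        est = estimate_trial_betas(sim.data, X)
        assert np.abs(est.data - sim.truth.data).max() < 1e-6

    def test_drift_columns_absorb_sinusoidal_drift(self, small_design):
        # slow drift inside the high-pass band: including the DCT drift
        # columns shrinks the amplitude-recovery error
        sp = SynthParams(n_voxels=5, noise_sd=0.0, seed=4)
        basis = make_pattern_basis(sp)
        sim = simulate_timeseries(
            small_design, basis, sp, tr=2.5, drift_amp=3.0, drift_period=300.0, rng=5
        )
        X_with = build_design_matrix(small_design, 2.5, highpass_cutoff=128.0)
        duration = len(sim.scan_times) * 2.5
        X_without = build_design_matrix(small_design, 2.5, highpass_cutoff=2 * duration + 1)
        err_with = np.abs(estimate_trial_betas(sim.data, X_with).data - sim.truth.data).max()
        err_without = np.abs(estimate_trial_betas(sim.data, X_without).data - sim.truth.data).max()
        assert err_with < err_without

    def test_ar1_noise_autocorrelated(self, small_design):
        sp = SynthParams(n_voxels=2, noise_sd=0.0, stimulus_amp=0.0, threat_amp=0.0, seed=6)
        basis = make_pattern_basis(sp)
        sim = simulate_timeseries(
            small_design, basis, sp, tr=2.5, scan_noise_sd=1.0, ar_coef=0.8, rng=7
        )
        x = sim.data[:, 0]
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r > 0.5
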