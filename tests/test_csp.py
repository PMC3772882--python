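"""CSP front-end: rejection, filtering, spatial filters, features, generator."""

import numpy as np
import pytest

from zlda import (
    SpatialFilterBank,
    SynthEEGConfig,
    TrialArray,
    bandpass_filter,
    fit_csp,
    fit_zlda,
    generate_synthetic_trials,
    log_variance_features,
    reject_artifacts,
    select_filter_pairs,
)
from zlda.csp import _class_covariances


def trials_with_peaks(peaks, fs=250.0):
    data = np.zeros((len(peaks), 2, 10))
    for i, pk in enumerate(peaks):
        data[i, 0, 0] = pk
    return TrialArray(data=data, fs=fs, labels=np.array(["a", "b"] * (len(peaks) // 2)))


def square_wave_trials(amps1, amps2, n_rep=4, n_samples=64):
    """Trials whose per-trial covariance is exactly diagonal.

    Channel 1 carries a +-a square wave, channel 2 a +-b wave at half the
    frequency; the two are orthogonal and zero-mean, so the covariance is
    diag(a^2, b^2) up to the common trace normalization.
    """
    s1 = np.tile([1.0, -1.0], n_samples // 2)
    s2 = np.tile([1.0, 1.0, -1.0, -1.0], n_samples // 4)
    data, labels = [], []
    for (a, b), name in (((amps1), "a"), ((amps2), "b")):
        for _ in range(n_rep):
            data.append(np.vstack([a * s1, b * s2]))
            labels.append(name)
    return TrialArray(data=np.array(data), fs=100.0, labels=np.array(labels))


class TestRejectArtifacts:
    @pytest.mark.parametrize("peak, kept", [(350.0, False), (299.0, True), (300.0, True)])
    def test_threshold_is_strict_exceedance(self, peak, kept):
        trials = trials_with_peaks([peak, 10.0])
        out = reject_artifacts(trials)
        assert (out.n_trials == 2) is kept

    def test_order_preserved(self):
        trials = trials_with_peaks([10.0, 400.0, 20.0, 30.0])
        out = reject_artifacts(trials)
        np.testing.assert_array_equal(out.data[:, 0, 0], [10.0, 20.0, 30.0])

    def test_all_contaminated_is_an_error(self):
        with pytest.raises(ValueError, match="no trials survive rejection"):
            reject_artifacts(trials_with_peaks([400.0, 500.0]))


class TestBandpass:
    def make_tone(self, freq, fs=250.0, n=2000):
        t = np.arange(n) / fs
        data = np.sin(2 * np.pi * freq * t)[None, None, :].repeat(2, axis=1)
        return TrialArray(data=data, fs=fs, labels=np.array(["a"]))

    def test_passband_tone_amplitude_preserved(self):
        out = bandpass_filter(self.make_tone(15.0), band=(8.0, 30.0))
        mid = out.data[0, 0, 500:1500]  # avoid filter edge transients
        assert np.ptp(mid) / 2 == pytest.approx(1.0, rel=0.05)

    def test_dc_offset_removed(self):
        trials = self.make_tone(15.0)
        shifted = TrialArray(data=trials.data * 0 + 5.0, fs=trials.fs, labels=trials.labels)
        out = bandpass_filter(shifted, band=(8.0, 30.0))
        assert np.max(np.abs(out.data[0, 0, 500:1500])) < 0.05

    @pytest.mark.parametrize("band", [(30.0, 8.0), (0.0, 30.0), (8.0, 200.0)])
    def test_invalid_bands_rejected(self, band):
        with pytest.raises(ValueError, match="band outside Nyquist range"):
            bandpass_filter(self.make_tone(15.0), band=band)


class TestFitCsp:
    def test_diagonal_class_covariances_solved_by_hand(self):
        """Class covs diag(4,1) vs diag(1,4): eigenvalues {0.8, 0.2}, axis filters."""
        trials = square_wave_trials((2.0, 1.0), (1.0, 2.0))
        bank = fit_csp(trials)
        np.testing.assert_allclose(bank.eigenvalues, [0.8, 0.2], atol=1e-10)
        # each filter aligns with a coordinate axis (up to sign/scale)
        for row, axis in zip(bank.filters, ([1.0, 0.0], [0.0, 1.0])):
            direction = row / np.linalg.norm(row)
            assert abs(np.dot(direction, axis)) == pytest.approx(1.0, abs=1e-10)

    def test_identical_class_covariances_are_nondiscriminative(self):
        trials = square_wave_trials((1.0, 1.0), (1.0, 1.0))
        bank = fit_csp(trials)
        np.testing.assert_allclose(bank.eigenvalues, [0.5, 0.5], atol=1e-10)

    def test_joint_diagonalization_identity(self, synth_trials):
        """Every filter w satisfies w'C1w = lambda and w'C1w + w'C2w = 1."""
        bank = fit_csp(synth_trials)
        C1, C2, _ = _class_covariances(synth_trials)
        for w, lam in zip(bank.filters, bank.eigenvalues):
            assert w @ C1 @ w == pytest.approx(lam, abs=1e-9)
            assert w @ C1 @ w + w @ C2 @ w == pytest.approx(1.0, abs=1e-9)

    def test_swapping_class_roles_mirrors_the_spectrum(self, synth_trials):
        bank = fit_csp(synth_trials, classes=("left", "right"))
        bank_flip = fit_csp(synth_trials, classes=("right", "left"))
        np.testing.assert_allclose(
            bank_flip.eigenvalues, (1.0 - bank.eigenvalues)[::-1], atol=1e-9
        )

    def test_rank_deficient_covariance_needs_shrinkage(self):
        cfg = SynthEEGConfig(
            n_channels=4,
            n_samples=100,
            n_trials_per_class=10,
            class1_source_vars=(4.0,),
            class2_source_vars=(1.0,),
            n_background=0,
            noise_sd_uv=0.0,
        )
        trials = generate_synthetic_trials(cfg, seed=0)
        with pytest.raises(ValueError, match="singular covariance"):
            fit_csp(trials)
        bank = fit_csp(trials, shrinkage=0.1)
        assert np.all(np.isfinite(bank.filters))


class TestSelectFilterPairs:
    def make_bank(self, eigenvalues):
        n = len(eigenvalues)
        return SpatialFilterBank(
            filters=np.eye(n), eigenvalues=np.asarray(eigenvalues, dtype=float)
        )

    def test_three_pairs_from_fifteen_channels(self, synth_trials):
        filters = select_filter_pairs(fit_csp(synth_trials), n_pairs=3)
        assert filters.shape == (6, 15)

    def test_extremes_of_the_spectrum_chosen(self):
        bank = self.make_bank([0.9, 0.7, 0.5, 0.3, 0.1])
        chosen = select_filter_pairs(bank, n_pairs=1)
        np.testing.assert_array_equal(chosen, np.eye(5)[[0, 4]])

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError, match="n_pairs"):
            select_filter_pairs(self.make_bank([0.8, 0.5, 0.2]), n_pairs=2)

    def test_selection_invariant_to_common_trial_rescaling(self, synth_trials):
        bank = fit_csp(synth_trials)
        scaled = TrialArray(
            data=synth_trials.data * 3.7, fs=synth_trials.fs, labels=synth_trials.labels
        )
        bank_scaled = fit_csp(scaled)
        np.testing.assert_allclose(bank_scaled.eigenvalues, bank.eigenvalues, atol=1e-9)
        f1 = select_filter_pairs(bank, n_pairs=3)
        f2 = select_filter_pairs(bank_scaled, n_pairs=3)
        for a, b in zip(f1, f2):
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert abs(cos) == pytest.approx(1.0, abs=1e-6)


class TestLogVarianceFeatures:
    def test_unit_variance_projection_maps_to_zero(self):
        data = np.tile([1.0, -1.0], 8)[None, None, :].repeat(2, axis=1)
        trials = TrialArray(data=data, fs=100.0, labels=np.array(["a"]))
        feats = log_variance_features(trials, np.array([[1.0, 0.0]]))
        assert feats[0, 0] == pytest.approx(0.0)  # population variance 1

    def test_trial_rescaling_adds_two_log_c(self, synth_trials):
        filters = select_filter_pairs(fit_csp(synth_trials), n_pairs=3)
        base = log_variance_features(synth_trials, filters)
        c = 2.5
        scaled = TrialArray(
            data=synth_trials.data * c, fs=synth_trials.fs, labels=synth_trials.labels
        )
        np.testing.assert_allclose(
            log_variance_features(scaled, filters), base + 2 * np.log(c), atol=1e-9
        )

    def test_feature_matrix_shape(self, synth_trials):
        filters = select_filter_pairs(fit_csp(synth_trials), n_pairs=3)
        feats = log_variance_features(synth_trials, filters)
        assert feats.shape == (synth_trials.n_trials, 6)

    def test_flat_projection_rejected(self):
        data = np.zeros((1, 2, 10))
        data[0, 1] = np.tile([1.0, -1.0], 5)
        trials = TrialArray(data=data, fs=100.0, labels=np.array(["a"]))
        with pytest.raises(ValueError, match="log of zero variance"):
            log_variance_features(trials, np.array([[1.0, 0.0]]))


class TestSyntheticTrials:
    def test_seeded_determinism(self):
        cfg = SynthEEGConfig(n_trials_per_class=5)
        a = generate_synthetic_trials(cfg, seed=3)
        b = generate_synthetic_trials(cfg, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_configured_variance_ratio_recovered_by_csp(self, synth_trials):
        """A 4:1 source variance flip should surface as a top eigenvalue near 0.8."""
        bank = fit_csp(synth_trials)
        assert bank.eigenvalues[0] == pytest.approx(0.8, abs=0.05)
        assert bank.eigenvalues[-1] == pytest.approx(0.2, abs=0.05)

    def test_end_to_end_pipeline_is_learnable(self, synth_trials):
        """reject -> band-pass -> CSP -> log-variance -> Z-LDA beats 90% held out."""
        test_trials = generate_synthetic_trials(SynthEEGConfig(), seed=8)
        train = bandpass_filter(reject_artifacts(synth_trials), band=(8.0, 30.0))
        test = bandpass_filter(reject_artifacts(test_trials), band=(8.0, 30.0))
        filters = select_filter_pairs(fit_csp(train), n_pairs=3)
        model = fit_zlda(log_variance_features(train, filters), train.labels)
        preds = model.predict(log_variance_features(test, filters))
        assert np.mean(preds == test.labels) > 0.90
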