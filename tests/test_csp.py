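"""CSP decomposition: covariances, whitening, joint diagonalization, features."""

import numpy as np
import pytest

from eegselect import (
    CSPError,
    CSPModel,
    EpochedEEG,
    SimConfig,
    fit_csp,
    normalized_covariance,
    simulate_mi,
    transform,
)
from eegselect.csp import _csp_from_covs


def naive_covariance(X):
    """Independent oracle: triple-loop X Xᵀ / trace."""
    n_ch, n_s = X.shape
    R = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            for t in range(n_s):
                R[i, j] += X[i, t] * X[j, t]
    return R / np.trace(R)


def white_noise_epochs(rng, scales_a, scales_b, n_trials=6, n_samples=2000):
    """Per-channel scaled white noise -> class covariances ~ diag(scales²)."""
    n_ch = len(scales_a)
    data, labels = [], []
    for lab, scales in ((0, scales_a), (1, scales_b)):
        for _ in range(n_trials):
            data.append(np.asarray(scales)[:, None]
                        * rng.standard_normal((n_ch, n_samples)))
            labels.append(lab)
    return EpochedEEG(data=np.stack(data), fs=100.0, labels=labels)


class TestNormalizedCovariance:
    def test_trace_is_one(self, rng):
        C = normalized_covariance(rng.standard_normal((5, 50)))
        assert np.trace(C) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-12)

    def test_orthogonal_equal_power_rows(self):
        X = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        assert np.allclose(normalized_covariance(X), np.diag([0.5, 0.5]))

    def test_matches_naive_oracle(self, rng):
        X = rng.standard_normal((4, 100))
        assert np.allclose(normalized_covariance(X), naive_covariance(X),
                           atol=1e-12)

    def test_zero_trial_rejected(self):
        with pytest.raises(CSPError, match="degenerate"):
            normalized_covariance(np.zeros((3, 10)))


class TestFitCSP:
    def test_identical_classes_give_half_eigenvalues(self, rng):
        trials = rng.standard_normal((4, 3, 200))
        epochs = EpochedEEG(
            data=np.concatenate([trials, trials]), fs=100.0,
            labels=[0, 0, 0, 0, 1, 1, 1, 1],
        )
        model = fit_csp(epochs, m_pairs=1)
        assert np.allclose(np.diag(model.LamA), 0.5, atol=1e-10)

    def test_two_channel_closed_form(self, rng):
        # class A covariance ∝ diag(4,1), class B ∝ diag(1,4):
        # after trace-normalization Ca=diag(.8,.2), Cb=diag(.2,.8), Cc=I,
        # so the whitened class-A eigenvalues are {0.8, 0.2}
        epochs = white_noise_epochs(rng, (2.0, 1.0), (1.0, 2.0),
                                    n_trials=8, n_samples=5000)
        model = fit_csp(epochs, m_pairs=1)
        assert np.diag(model.LamA) == pytest.approx([0.8, 0.2], abs=0.02)

    def test_whitening_and_eigenvalue_partition(self, rng):
        # defining properties on random instances of varying size
        for n_ch in (2, 5, 9):
            epochs = EpochedEEG(
                data=rng.standard_normal((8, n_ch, 100)), fs=100.0,
                labels=[0, 1] * 4,
            )
            m = fit_csp(epochs, m_pairs=2)
            assert np.allclose(m.P @ m.Cc @ m.P.T, np.eye(n_ch), atol=1e-8)
            assert np.allclose(m.LamA + m.LamB, np.eye(n_ch), atol=1e-8)
            assert np.allclose(m.Cc, m.Ca + m.Cb, atol=1e-10)
            assert np.all(np.diff(np.diag(m.LamA)) <= 1e-12)  # descending
            m_eff = min(2, n_ch // 2)
            assert m.selected_cols == tuple(range(m_eff)) + tuple(
                range(n_ch - m_eff, n_ch))

    def test_single_class_rejected(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((4, 3, 50)), fs=100.0,
                            labels=[0, 0, 0, 0])
        with pytest.raises(CSPError, match="2 classes"):
            fit_csp(epochs)

    def test_rank_deficient_subset_still_decomposes(self, rng):
        # duplicated channel -> singular composite covariance; ridge handles it
        base = rng.standard_normal((6, 2, 80))
        data = np.concatenate([base, base[:, :1, :]], axis=1)
        epochs = EpochedEEG(data=data, fs=100.0, labels=[0, 1, 0, 1, 0, 1])
        model = fit_csp(epochs, m_pairs=1)
        assert np.all(np.isfinite(model.W))


class TestTransform:
    def test_identity_filters_return_log_channel_variance(self, rng):
        n_ch = 3
        data = rng.standard_normal((2, n_ch, 400)) * np.array(
            [1.0, 2.0, 0.5])[None, :, None]
        epochs = EpochedEEG(data=data, fs=100.0, labels=[0, 1])
        eye = np.eye(n_ch)
        model = CSPModel(
            Ca=eye / n_ch, Cb=eye / n_ch, Cc=2 * eye / n_ch, U=eye,
            lam=np.ones(n_ch), P=eye, Sa=eye / 2, Sb=eye / 2, V=eye,
            LamA=eye / 2, LamB=eye / 2, W=eye, m_pairs=1,
            selected_cols=tuple(range(n_ch)),
        )
        feats = transform(model, epochs)
        expected = np.log(np.mean(data**2, axis=2))
        assert np.allclose(feats, expected, atol=1e-12)

    def test_matches_stepwise_oracle(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((5, 6, 120)), fs=100.0,
                            labels=[0, 1, 0, 1, 0])
        model = fit_csp(epochs, m_pairs=2)
        feats = transform(model, epochs)
        assert feats.shape == (5, 4)
        for t in range(5):
            for f, col in enumerate(model.selected_cols):
                z = model.W[:, col] @ epochs.data[t]
                expected = np.log(np.mean(z * z))
                assert feats[t, f] == pytest.approx(expected, abs=1e-10)

    def test_channel_count_mismatch(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((4, 6, 50)), fs=100.0,
                            labels=[0, 1, 0, 1])
        model = fit_csp(epochs, m_pairs=1)
        with pytest.raises(CSPError, match="channels"):
            transform(model, EpochedEEG(data=rng.standard_normal((2, 4, 50)),
                                        fs=100.0, labels=[0, 1]))

    def test_zero_variance_projection_warns_not_raises(self):
        eye = np.eye(2)
        model = CSPModel(
            Ca=eye / 2, Cb=eye / 2, Cc=eye, U=eye, lam=np.ones(2), P=eye,
            Sa=eye / 2, Sb=eye / 2, V=eye, LamA=eye / 2, LamB=eye / 2,
            W=eye, m_pairs=1, selected_cols=(0, 1),
        )
        epochs = EpochedEEG(data=np.zeros((1, 2, 10)), fs=100.0, labels=[0])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            feats = transform(model, epochs)
        assert np.all(np.isfinite(feats))


class TestCSPProperties:
    def test_channel_permutation_equivariance(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((6, 5, 300)), fs=100.0,
                            labels=[0, 1] * 3)
        perm = np.array([3, 0, 4, 1, 2])
        permuted = EpochedEEG(data=epochs.data[:, perm, :], fs=100.0,
                              labels=epochs.labels)
        f1 = transform(fit_csp(epochs, 2), epochs)
        f2 = transform(fit_csp(permuted, 2), permuted)
        assert np.allclose(f1, f2, atol=1e-8)

    def test_class_swap_reverses_features(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((6, 4, 300)), fs=100.0,
                            labels=[0, 1] * 3)
        swapped = EpochedEEG(data=epochs.data, fs=100.0,
                             labels=1 - epochs.labels)
        f1 = transform(fit_csp(epochs, 2), epochs)
        f2 = transform(fit_csp(swapped, 2), swapped)
        assert np.allclose(f1, f2[:, ::-1], atol=1e-8)

    def test_top_filter_weights_most_discriminative_channel(self, rng):
        # channel 2 has maximal between-class variance difference
        scales_a = (1.0, 1.0, 3.0, 1.0)
        scales_b = (1.0, 1.0, 0.3, 1.0)
        epochs = white_noise_epochs(rng, scales_a, scales_b,
                                    n_trials=10, n_samples=3000)
        model = fit_csp(epochs, m_pairs=1)
        assert int(np.argmax(np.abs(model.W[:, 0]))) == 2

    def test_fit_from_covs_matches_fit_from_epochs(self, rng):
        epochs = EpochedEEG(data=rng.standard_normal((6, 4, 100)), fs=100.0,
                            labels=[0, 1] * 3)
        m1 = fit_csp(epochs, 2)
        m2 = _csp_from_covs(m1.Ca, m1.Cb, 2)
        assert np.array_equal(m1.W, m2.W)

    def test_model_save_load_round_trip(self, rng, tmp_path):
        epochs = EpochedEEG(data=rng.standard_normal((4, 3, 80)), fs=100.0,
                            labels=[0, 1, 0, 1])
        model = fit_csp(epochs, 1)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = CSPModel.load(path)
        assert np.array_equal(loaded.W, model.W)
        assert loaded.selected_cols == model.selected_cols
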