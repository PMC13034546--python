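"""RSA: z-scoring, condition patterns, PCA denoising, Mahalanobis RDMs,
model RDMs, Kendall Tau-A, time courses and searchlight."""

import numpy as np
import pandas as pd
import pytest

from covis.containers import EpochArray
from covis.montage import ROI_MAP
from covis.rsa import (
    condition_labels,
    fit_condition_patterns,
    kendall_tau_a,
    lower_triangle,
    mahalanobis_rdm,
    model_rdm_coherence,
    model_rdm_context,
    noise_covariance,
    pca_denoise,
    rsa_timecourse,
    searchlight_rsa,
    zscore_epochs,
)
from covis.synth import GenParams, build_design, simulate_behavior, simulate_eeg


def tau_a_enumeration(a, b):
    """Exhaustive 990-pair Tau-A oracle over two 45-vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    num = 0
    n = a.size
    for i in range(n):
        for j in range(i + 1, n):
            num += np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
    return num / (n * (n - 1) / 2)


def make_epochs(data, channels=None, fs=250.0, t0=0.0):
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    return EpochArray(
        data=data,
        times_ms=t0 + np.arange(n_t) * 1000.0 / fs,
        channel_names=channels,
        trial_ids=np.arange(1, n_tr + 1),
        fs_hz=fs,
        alignment="stimulus",
    )


class TestZscore:
    def test_two_trials_give_unit_values(self):
        data = np.stack([np.full((3, 5), 1.0), np.full((3, 5), 4.0)])
        out = zscore_epochs(make_epochs(data))
        np.testing.assert_allclose(np.abs(out.data), 1.0)

    def test_moments(self, rng):
        data = rng.normal(2.0, 3.0, size=(40, 4, 30))
        out = zscore_epochs(make_epochs(data))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-10)

    def test_matches_loop_oracle(self, rng):
        data = rng.normal(size=(10, 3, 8))
        out = zscore_epochs(make_epochs(data))
        for ch in range(3):
            for tt in range(8):
                col = data[:, ch, tt]
                ref = (col - col.mean()) / col.std()
                np.testing.assert_allclose(out.data[:, ch, tt], ref,
                                           atol=1e-12)

    def test_zero_variance_cell_named(self):
        data = np.random.default_rng(0).normal(size=(6, 2, 4))
        data[:, 1, 2] = 5.0
        with pytest.raises(ValueError, match="ch1"):
            zscore_epochs(make_epochs(data))


class TestConditionPatterns:
    @staticmethod
    def _design(n_per_cond=3):
        rows = []
        for ctx, coh in condition_labels():
            for _ in range(n_per_cond):
                rows.append({"coherence": coh, "context": ctx,
                             "direction": "left"})
        df = pd.DataFrame(rows)
        df.insert(0, "trial_id", np.arange(1, len(df) + 1))
        return df

    def test_balanced_onehot_closed_form(self):
        """Condition-constant data: minimum-norm betas equal the condition
        means shifted by 10/11 of the grand mean (pinv closed form)."""
        design = self._design(3)
        c = np.arange(10, dtype=float)  # condition k has constant value k
        data = np.repeat(c, 3)[:, None, None] * np.ones((30, 2, 4))
        betas, resid = fit_condition_patterns(make_epochs(data), design)
        expected = c - (10.0 / 11.0) * c.mean()
        for tt in range(4):
            for ch in range(2):
                np.testing.assert_allclose(betas[tt, :, ch], expected,
                                           atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_all_zero_data(self):
        design = self._design(2)
        betas, resid = fit_condition_patterns(
            make_epochs(np.zeros((20, 2, 3))), design
        )
        np.testing.assert_allclose(betas, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        design = self._design(3)
        data = rng.normal(size=(30, 2, 5))
        betas, resid = fit_condition_patterns(make_epochs(data), design)
        # explicit pinv via the normal equations on the 30-trial toy set
        X = np.zeros((30, 11))
        X[:, 0] = 1.0
        for i in range(30):
            X[i, 1 + i // 3] = 1.0
        P = np.linalg.pinv(X.T @ X) @ X.T
        for ch in range(2):
            for tt in range(5):
                ref = P @ data[:, ch, tt]
                np.testing.assert_allclose(betas[tt, :, ch], ref[1:],
                                           atol=1e-8)
                np.testing.assert_allclose(
                    resid[:, ch, tt], data[:, ch, tt] - X @ ref, atol=1e-8
                )

    def test_beta_differences_are_condition_mean_differences(self, rng):
        # the intercept ambiguity cancels in pairwise differences
        design = self._design(4)
        data = rng.normal(size=(40, 3, 2))
        betas, _ = fit_condition_patterns(make_epochs(data), design)
        cond_means = data.reshape(10, 4, 3, 2).mean(axis=1)
        for tt in range(2):
            d_beta = betas[tt][:, None, :] - betas[tt][None, :, :]
            d_mean = cond_means[:, None, :, tt] - cond_means[None, :, :, tt]
            np.testing.assert_allclose(d_beta, d_mean, atol=1e-8)

    def test_missing_condition_error(self):
        design = self._design(2)
        design = design[design["coherence"] != 3.2].reset_index(drop=True)
        with pytest.raises(ValueError, match="3.2"):
            fit_condition_patterns(
                make_epochs(np.zeros((len(design), 2, 3))), design
            )


class TestPcaDenoise:
    def test_rank1_unchanged(self, rng):
        m = np.outer(rng.normal(size=10), rng.normal(size=8))
        out = pca_denoise(m)
        np.testing.assert_allclose(out, m, atol=1e-10)

    def test_full_rank_drops_to_rank9(self, rng):
        m = rng.normal(size=(10, 12))
        out = pca_denoise(m)
        s_in = np.linalg.svd(m, compute_uv=False)
        assert np.linalg.matrix_rank(out, tol=1e-8) == 9
        # Eckart-Young: the removal error is exactly the smallest singular value
        assert np.linalg.norm(m - out, "fro") == pytest.approx(s_in[-1])

    def test_idempotent_direction(self, rng):
        m = rng.normal(size=(10, 6))
        once = pca_denoise(m)
        assert np.linalg.matrix_rank(once, tol=1e-8) == 5
        # the smallest singular value is now ~0, so a second pass is a no-op
        np.testing.assert_allclose(pca_denoise(once), once, atol=1e-10)


class TestNoiseCovariance:
    def test_white_residuals_near_identity(self):
        rng = np.random.default_rng(5)
        r = rng.normal(0, 1.0, size=(10_000, 6))
        S = noise_covariance(r, shrinkage=0.0)
        np.testing.assert_allclose(S, np.eye(6), atol=0.05)

    def test_full_shrinkage_is_diagonal(self, rng):
        r = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        S = noise_covariance(r, shrinkage=1.0)
        np.testing.assert_allclose(S, np.diag(np.diag(S)), atol=1e-12)

    def test_positive_definite_for_any_positive_shrinkage(self, rng):
        r = rng.normal(size=(8, 12))  # fewer trials than channels
        for gamma in (0.05, 0.3, 0.9):
            S = noise_covariance(r, shrinkage=gamma)
            np.linalg.cholesky(S)  # raises if not PD


class TestMahalanobisRdm:
    def test_identity_cov_is_euclidean(self, rng):
        b = rng.normal(size=(10, 5))
        rdm = mahalanobis_rdm(b, np.eye(5))
        from scipy.spatial.distance import pdist, squareform

        np.testing.assert_allclose(rdm, squareform(pdist(b)), atol=1e-10)

    def test_two_channel_closed_form(self):
        b = np.zeros((10, 2))
        b[1] = [2.0, 0.0]
        rdm = mahalanobis_rdm(b, np.diag([4.0, 1.0]))
        assert rdm[0, 1] == pytest.approx(1.0)  # sqrt(4/4)

    def test_matches_per_pair_solve_oracle(self, rng):
        b = rng.normal(size=(10, 8))
        A = rng.normal(size=(8, 8))
        cov = A @ A.T + 0.5 * np.eye(8)
        rdm = mahalanobis_rdm(b, cov)
        assert np.allclose(rdm, rdm.T) and np.allclose(np.diag(rdm), 0.0)
        for i in range(10):
            for j in range(i + 1, 10):
                d = b[i] - b[j]
                ref = np.sqrt(d @ np.linalg.solve(cov, d))
                assert rdm[i, j] == pytest.approx(ref, rel=1e-10)

    def test_singular_cov_advises_shrinkage(self):
        b = np.zeros((10, 3))
        with pytest.raises(ValueError, match="shrinkage"):
            mahalanobis_rdm(b, np.zeros((3, 3)))


class TestModelRdms:
    def test_coherence_model_entries(self):
        m = model_rdm_coherence()
        labels = condition_labels()
        assert m.shape == (10, 10)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)
        for i, (_, ci) in enumerate(labels):
            for j, (_, cj) in enumerate(labels):
                assert m[i, j] == pytest.approx(abs(ci - cj) / 51.2)
        assert m.max() == pytest.approx(48.0 / 51.2) == pytest.approx(0.9375)
        # equal-coherence pairs across contexts are zero
        assert m[0, 5] == 0.0

    def test_context_model_entries(self):
        m = model_rdm_context()
        tri = lower_triangle(m)
        assert sorted(np.unique(tri)) == [0.0, 1.0]
        assert (tri == 0).sum() == 20  # C(5,2) within each of 2 contexts
        assert (tri == 1).sum() == 25  # 5 x 5 between contexts
        assert m[0, 5] == 1.0  # same coherence, different context
        assert m[0, 1] == 0.0  # same context, different coherence

    def test_context_identity_variant(self):
        m = model_rdm_context(block="identity")
        assert lower_triangle(m).sum() == 5.0  # only equal-coherence pairs
        assert m[0, 5] == 1.0 and m[0, 6] == 0.0


class TestKendallTauA:
    def test_self_similarity_of_tie_free(self, rng):
        r = rng.normal(size=(10, 10))
        rdm = r @ r.T
        np.fill_diagonal(rdm, 0.0)
        rdm = (rdm + rdm.T) / 2
        assert kendall_tau_a(rdm, rdm) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self, rng):
        a = np.zeros((10, 10))
        i, j = np.tril_indices(10, -1)
        vals = rng.permutation(45).astype(float)
        a[i, j] = vals
        a += a.T
        b = np.zeros((10, 10))
        b[i, j] = -vals
        b += b.T
        assert kendall_tau_a(a, b) == pytest.approx(-1.0)

    def test_context_model_self_similarity_500_over_990(self):
        m = model_rdm_context()
        tau = kendall_tau_a(m, m)
        assert tau == pytest.approx(500.0 / 990.0)
        assert tau == pytest.approx(tau_a_enumeration(lower_triangle(m),
                                                      lower_triangle(m)))

    def test_matches_enumeration_oracle(self, rng):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        i, j = np.tril_indices(10, -1)
        a[i, j] = rng.integers(0, 5, 45)
        b[i, j] = rng.normal(size=45)
        a += a.T
        b += b.T
        assert kendall_tau_a(a, b) == pytest.approx(
            tau_a_enumeration(a[i, j], b[i, j])
        )

    def test_model_cross_similarity_fixed(self):
        # the coherence and context models are weakly anticorrelated
        tau = kendall_tau_a(model_rdm_coherence(), model_rdm_context())
        assert tau == pytest.approx(-0.101, abs=1e-3)

    def test_invariant_under_monotone_transform(self, rng):
        r = rng.normal(size=(10, 6))
        cov = np.eye(6)
        rdm = mahalanobis_rdm(r, cov)
        model = model_rdm_coherence()
        assert kendall_tau_a(rdm**2, model) == pytest.approx(
            kendall_tau_a(rdm, model)
        )


class TestRsaTimecourse:
    @staticmethod
    def _cohort_design(npt=4, seed=0):
        design = build_design(npt, n_blocks=1, seed=seed)
        gp_beh = GenParams(seed=seed)
        behavior = simulate_behavior(design, gp_beh)
        return design, behavior

    def test_context_elevated_inside_window_only(self):
        """Pattern injected in a window; with a pre-window baseline the
        context tau is high inside and near zero outside."""
        design, behavior = self._cohort_design(npt=4, seed=21)
        gp = GenParams(noise_sd=1.0, cpp_gain=0.0, context_gain=4.0,
                       context_window_ms=(-400.0, 600.0), seed=21)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 1500.0))
        res = rsa_timecourse(epochs, design,
                             baseline_ms=(-1000.0, -600.0), stride=4)
        tau = res.tau["context"]
        inside = (res.times_ms >= -100) & (res.times_ms <= 600)
        outside = (res.times_ms < -500) | (res.times_ms > 800)
        assert tau[inside].mean() > 0.3
        assert abs(tau[outside].mean()) < 0.05

    def test_coherence_elevated_post_stimulus_only(self):
        design, behavior = self._cohort_design(npt=4, seed=22)
        gp = GenParams(noise_sd=1.0, cpp_gain=0.2, context_gain=0.0, seed=22)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 1500.0))
        res = rsa_timecourse(epochs, design,
                             baseline_ms=(-1000.0, -600.0), stride=4)
        tau = res.tau["coherence"]
        post = (res.times_ms >= 300) & (res.times_ms <= 700)
        pre = res.times_ms < 0
        assert tau[post].mean() > 0.3
        assert abs(tau[pre].mean()) < 0.05

    def test_pure_noise_fluctuates_around_zero(self):
        taus = []
        for s in range(8):
            design, behavior = self._cohort_design(npt=2, seed=30 + s)
            gp = GenParams(noise_sd=5.0, cpp_gain=0.0, context_gain=0.0,
                           seed=30 + s)
            epochs = simulate_eeg(design, behavior, gp,
                                  epoch_window_ms=(-200.0, 700.0))
            res = rsa_timecourse(epochs, design, stride=8,
                                 baseline_ms=(-200.0, -100.0))
            taus.append(res.tau["context"])
        taus = np.array(taus)
        mean = taus.mean(axis=0)
        se = taus.std(axis=0, ddof=1) / np.sqrt(taus.shape[0])
        frac_within = np.mean(np.abs(mean) <= 2 * se)
        assert frac_within >= 0.80
        assert abs(mean.mean()) < 0.05

    def test_rdms_symmetric_zero_diagonal(self):
        design, behavior = self._cohort_design(npt=2, seed=40)
        gp = GenParams(noise_sd=2.0, context_window_ms=(-900.0, 600.0),
                       seed=40)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 700.0))
        res = rsa_timecourse(epochs, design, stride=16, keep_rdms=True)
        assert np.allclose(res.rdms, np.swapaxes(res.rdms, 1, 2))
        assert np.allclose(res.rdms.diagonal(axis1=1, axis2=2), 0.0)
        for name in res.tau:
            assert np.all(np.abs(res.tau[name]) <= 1.0)


class TestSearchlight:
    def test_all_channel_roi_equals_whole_sensor(self):
        design = build_design(2, n_blocks=1, seed=50)
        gp = GenParams(noise_sd=3.0, context_window_ms=(-900.0, 600.0),
                       seed=50)
        behavior = simulate_behavior(design, gp)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 700.0))
        whole = rsa_timecourse(epochs, design, stride=16)
        sl = searchlight_rsa(
            epochs, design,
            roi_map={"all": tuple(epochs.channel_names)}, stride=16,
        )
        for m in whole.tau:
            np.testing.assert_allclose(sl["all"].tau[m], whole.tau[m],
                                       atol=1e-12)

    def test_frontal_injection_localized(self):
        design = build_design(4, n_blocks=1, seed=51)
        gp0 = GenParams(seed=51)
        behavior = simulate_behavior(design, gp0)
        gp = GenParams(noise_sd=1.0, cpp_gain=0.0, context_gain=0.0, seed=51)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 700.0))
        # inject a context pattern on the frontal electrodes only
        rng = np.random.default_rng(51)
        frontal_idx = [epochs.channel_index(e) for e in ROI_MAP["Frontal"]]
        pattern = rng.normal(size=len(frontal_idx)) * 4.0
        sign = np.where(design["context"] == "public", 1.0, -1.0)
        window = (epochs.times_ms >= -400) & (epochs.times_ms <= 400)
        for k, ch in enumerate(frontal_idx):
            epochs.data[:, ch, window] += np.outer(
                sign * pattern[k], np.ones(window.sum())
            )
        sl = searchlight_rsa(epochs, design, stride=4,
                             baseline_ms=(-1000.0, -600.0))
        sel_win = (sl["Frontal"].times_ms >= -200) & (
            sl["Frontal"].times_ms <= 300
        )
        assert (
            sl["Frontal"].tau["context"][sel_win].mean()
            > sl["Occipital"].tau["context"][sel_win].mean() + 0.2
        )

    def test_unknown_electrode_named(self):
        design = build_design(2, n_blocks=1, seed=52)
        gp = GenParams(noise_sd=2.0, context_window_ms=(-900.0, 600.0),
                       seed=52)
        behavior = simulate_behavior(design, gp)
        epochs = simulate_eeg(design, behavior, gp,
                              montage=["CPz", "Pz", "CP1", "CP2"],
                              epoch_window_ms=(-1000.0, 700.0))
        with pytest.raises(ValueError, match="AF7"):
            searchlight_rsa(epochs, design,
                            roi_map={"Frontal": ("AF7", "AF3")})

    def test_empty_roi_rejected(self):
        design = build_design(2, n_blocks=1, seed=53)
        gp = GenParams(noise_sd=2.0, context_window_ms=(-900.0, 600.0),
                       seed=53)
        behavior = simulate_behavior(design, gp)
        epochs = simulate_eeg(design, behavior, gp,
                              epoch_window_ms=(-1000.0, 700.0))
        with pytest.raises(ValueError, match="empty"):
            searchlight_rsa(epochs, design, roi_map={"nothing": ()})
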