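"""Minimum-norm/dSPM inverse: closed-form oracle, limits, calibration, ROIs."""

from dataclasses import replace

import numpy as np
import pytest

from emdecode.inverse import (
    ROISet,
    apply_inverse,
    estimate_noise_cov,
    make_inverse,
    roi_timecourse,
)
from emdecode.synth import (
    NoiseModel,
    default_patches,
    make_toy_lead_field,
    simulate_participant,
    three_source_spec,
)


class TestNoiseCov:
    def test_iid_noise_approaches_identity(self, rng):
        segs = rng.standard_normal((4, 6, 20000))
        cov = estimate_noise_cov(segs, shrinkage=0.0).cov
        assert np.allclose(np.diag(cov), 1.0, atol=0.05)
        off = cov[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_full_shrinkage_is_diagonal(self, rng):
        segs = rng.standard_normal((3, 5, 500))
        cov = estimate_noise_cov(segs, shrinkage=1.0).cov
        assert np.allclose(cov, np.diag(np.diag(cov)))

    def test_known_correlation_recovered(self, rng):
        r = 0.6
        L = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
        segs = np.einsum("ij,sjt->sit", L, rng.standard_normal((2, 2, 5000)))
        cov = estimate_noise_cov(segs, shrinkage=0.0).cov
        assert cov[0, 1] == pytest.approx(r, abs=0.05)


class TestMakeInverse:
    def test_matches_closed_form_matrix_oracle(self, rng):
        g = rng.standard_normal((10, 4))
        c = np.cov(rng.standard_normal((10, 300)))
        lam2 = 1 / 9
        inv = make_inverse(g, c, lam2)
        # direct dense evaluation of M = G'(GG' + lam2 C)^-1, entrywise dSPM
        m_ref = g.T @ np.linalg.inv(g @ g.T + lam2 * c)
        assert np.allclose(inv.kernel, m_ref)
        for j in range(4):
            expected = np.sqrt(m_ref[j] @ c @ m_ref[j])
            assert inv.dspm_norm[j] == pytest.approx(expected, rel=1e-10)

    def test_orthogonal_limit_recovers_sources(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        inv = make_inverse(q, np.eye(8), 1e-10)
        s = rng.standard_normal((8, 20))
        rec = apply_inverse(q @ s, inv, dspm=False).data
        assert np.allclose(rec, s, atol=1e-6)

    def test_large_lambda_shrinks_kernel_to_zero(self, rng):
        g = rng.standard_normal((10, 3))
        inv_small = make_inverse(g, np.eye(10), 1e-3)
        inv_large = make_inverse(g, np.eye(10), 1e6)
        assert np.linalg.norm(inv_large.kernel) < 1e-4 * np.linalg.norm(inv_small.kernel)

    def test_singular_system_advises_regularization(self, rng):
        g = np.zeros((6, 2))
        g[:, 0] = 1.0
        g[:, 1] = 1.0  # rank-1 lead field, lambda2=0
        with pytest.raises(np.linalg.LinAlgError, match="lambda2"):
            make_inverse(g, np.eye(6), 0.0)


class TestApplyInverse:
    def test_zero_in_zero_out(self, rng):
        g = rng.standard_normal((8, 3))
        inv = make_inverse(g, np.eye(8))
        assert np.allclose(apply_inverse(np.zeros((8, 10)), inv).data, 0.0)

    def test_linearity_without_normalization(self, rng):
        g = rng.standard_normal((8, 3))
        inv = make_inverse(g, np.eye(8))
        x = rng.standard_normal((8, 15))
        s1 = apply_inverse(x, inv, dspm=False).data
        s2 = apply_inverse(2 * x, inv, dspm=False).data
        assert np.allclose(s2, 2 * s1)

    def test_channel_mismatch_reported(self, rng):
        inv = make_inverse(rng.standard_normal((8, 3)), np.eye(8))
        with pytest.raises(ValueError, match="channel mismatch"):
            apply_inverse(np.zeros((5, 10)), inv)

    def test_dspm_noise_calibration_unit_variance(self, rng):
        """Applying the inverse to noise drawn from C gives ~unit dSPM variance."""
        lf = make_toy_lead_field(40, default_patches(), 0)
        c = 0.3 * np.eye(40)
        inv = make_inverse(lf, c, 1 / 9)
        noise = np.sqrt(0.3) * rng.standard_normal((40, 50000))
        s = apply_inverse(noise, inv, dspm=True).data
        assert np.allclose(s.var(axis=1), 1.0, atol=0.05)

    def test_peak_dspm_in_generating_patch(self):
        """Noiseless three-source simulation localizes to the right patches."""
        spec = three_source_spec(
            n_sensors=60, n_trials_per_condition=4, n_participants=2,
            noise=NoiseModel(sensor_white_sd=0.0, background_scale=0.0),
        )
        lf = spec.lead_field
        inv = make_inverse(lf, np.eye(60), 1 / 9)
        for keep in lf.source_labels:
            solo = replace(spec, sources=[s for s in spec.sources if s.label == keep])
            ep, _ = simulate_participant(solo, 5)
            stc = apply_inverse(ep.data.mean(axis=0), inv, dspm=True, fs=200.0, tmin=-100.0)
            burst = (stc.times >= 80) & (stc.times <= 480)
            peaks = np.max(np.abs(stc.data[:, burst]), axis=1)
            assert stc.source_labels[int(np.argmax(peaks))] == keep

    def test_decomposition_and_inverse_commute(self, rng):
        """For a fixed linear kernel, EMD-then-invert equals invert-then-EMD
        up to sifting tolerance when sources outnumber... (kernel row mix)."""
        from emdecode.memd import masking_emd

        lf = make_toy_lead_field(12, default_patches(), 0)
        inv = make_inverse(lf, np.eye(12), 1 / 9)
        spec = three_source_spec(
            n_sensors=12, n_trials_per_condition=2, n_participants=2,
            noise=NoiseModel(sensor_white_sd=0.0, background_scale=0.0),
        )
        ep, _ = simulate_participant(spec, 3)
        x = ep.data[0]  # channels x samples
        # source trace via kernel, then decompose
        src_first = inv.kernel[2] @ x
        s1 = masking_emd(src_first, 200.0, 8)
        # decompose each channel, then mix IMF k through the kernel row
        per_chan = np.stack([masking_emd(x[ch], 200.0, 8).imfs[:5] for ch in range(12)])
        for k in range(3, 5):
            mixed = inv.kernel[2] @ per_chan[:, k, :]
            if k < s1.n_imfs:
                c = np.corrcoef(mixed, s1.imfs[k])[0, 1]
                # orders agree on the dominant band content, not sample-exactly
                assert c > 0.8


class TestROI:
    def test_single_source_roi_is_identity(self, rng):
        from emdecode.inverse import SourceEstimate

        stc = SourceEstimate(rng.standard_normal((3, 40)), ["a", "b", "c"], 200.0, -100.0)
        out = roi_timecourse(stc, ROISet({"solo": [1]}), reduce="mean")
        assert np.array_equal(out["solo"], stc.data[1])

    def test_opposed_sources_cancel_under_mean_not_absmean(self):
        from emdecode.inverse import SourceEstimate

        a = np.sin(np.linspace(0, 6, 50))
        stc = SourceEstimate(np.vstack([a, -a]), ["p", "q"], 200.0, 0.0)
        rois = ROISet({"pair": [0, 1]})
        assert np.allclose(roi_timecourse(stc, rois, "mean")["pair"], 0.0)
        assert np.allclose(roi_timecourse(stc, rois, "abs-mean")["pair"], np.abs(a))

    def test_empty_roi_rejected(self, rng):
        from emdecode.inverse import SourceEstimate

        stc = SourceEstimate(rng.standard_normal((2, 10)), ["a", "b"], 200.0, 0.0)
        with pytest.raises(ValueError, match="empty"):
            roi_timecourse(stc, ROISet({"nothing": []}))

    def test_simulated_frontal_roi_carries_theta(self):
        """The right-inferior-frontal ROI trace of the simulation is
        theta-dominated after decomposition."""
        from emdecode.hht import dominant_frequency, marginal_spectrum
        from emdecode.memd import masking_emd

        spec = three_source_spec(
            n_sensors=40, n_trials_per_condition=6, n_participants=2,
            noise=NoiseModel(sensor_white_sd=0.05, background_scale=0.1),
        )
        lf = spec.lead_field
        ep, _ = simulate_participant(spec, 21)
        inv = make_inverse(lf, np.eye(40) * 0.01, 1 / 9)
        stc = apply_inverse(ep.data.mean(axis=0), inv, dspm=True, fs=200.0, tmin=-100.0)
        roi = roi_timecourse(stc, ROISet({"ifg-rh": [2]}), "mean")["ifg-rh"]
        s = masking_emd(roi, 200.0, 8)
        energies = [np.sum(s.imf(k) ** 2) for k in range(1, s.n_imfs + 1)]
        carrier = s.imf(int(np.argmax(energies)) + 1)
        freq = dominant_frequency(marginal_spectrum(carrier, 200.0))
        assert freq == pytest.approx(7.0, abs=1.0)
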