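"""Q-ball reconstruction: SH basis, Funk-Radon transform, peaks, DTI."""

import numpy as np
import pytest
from scipy.special import roots_legendre

from lopdwi import phantom, recon, sampling
from lopdwi.core import DWIVolume

from conftest import axis_angle_deg


@pytest.fixture(scope="module")
def sphere():
    return recon.default_sphere(4)


def tensor_signal(directions, b, evals, evecs=np.eye(3)):
    """Single-tensor signal exp(-b g^T D g)."""
    D = evecs @ np.diag(evals) @ evecs.T
    return np.exp(-b * np.einsum("ni,ij,nj->n", directions, D, directions))


class TestSHBasis:
    def test_order_zero_is_constant(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(30, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        basis = recon.sh_design_matrix(0, d)
        np.testing.assert_allclose(basis.B, 1.0 / np.sqrt(4 * np.pi), atol=1e-12)

    def test_order_eight_has_45_columns(self, spiral_hemi):
        basis = recon.sh_design_matrix(8, spiral_hemi.directions)
        assert basis.B.shape == (82, 45)
        assert basis.laplace_beltrami[0] == 0.0
        assert basis.laplace_beltrami[-1] == 8 ** 2 * 9 ** 2

    def test_odd_order_rejected(self, spiral_hemi):
        with pytest.raises(ValueError):
            recon.sh_design_matrix(3, spiral_hemi.directions)

    def test_orthonormal_under_spherical_quadrature(self):
        # Gauss-Legendre in cos(theta) x trapezoid in phi integrates
        # band-limited spherical polynomials exactly
        xs, ws = roots_legendre(40)
        theta = np.arccos(xs)
        phi = np.linspace(0.0, 2 * np.pi, 80, endpoint=False)
        T, P = np.meshgrid(theta, phi, indexing="ij")
        W = np.repeat(ws[:, None], phi.size, axis=1) * (2 * np.pi / phi.size)
        dirs = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P),
                         np.cos(T)], axis=-1).reshape(-1, 3)
        basis = recon.sh_design_matrix(8, dirs)
        G = basis.B.T @ (W.reshape(-1, 1) * basis.B)
        np.testing.assert_allclose(G, np.eye(45), atol=1e-3)


class TestFitSH:
    def test_exact_recovery_without_regularization(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(200, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        basis = recon.sh_design_matrix(8, d)
        c_true = rng.normal(size=45)
        s = basis.B @ c_true
        c_fit = recon.fit_sh_regularized(s, basis, lambda_reg=0.0)
        np.testing.assert_allclose(c_fit, c_true, atol=1e-8)

    def test_huge_regularization_kills_high_degrees(self, spiral_hemi):
        rng = np.random.default_rng(2)
        basis = recon.sh_design_matrix(8, spiral_hemi.directions)
        s = np.abs(rng.normal(size=82)) + 0.2
        c = recon.fit_sh_regularized(s, basis, lambda_reg=1e6)
        assert np.abs(c[1:]).max() < 1e-4
        # l = 0 is unpenalized: recovers the spherical mean
        assert c[0] * float(basis.B[0, 0]) == pytest.approx(s.mean(), rel=0.05)

    def test_illposed_unregularized_fit_rejected(self):
        d = np.random.default_rng(3).normal(size=(20, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        basis = recon.sh_design_matrix(8, d)
        with pytest.raises(ValueError):
            recon.fit_sh_regularized(np.ones(20), basis, lambda_reg=0.0)

    def test_regularization_improves_held_out_fit(self, spiral_hemi):
        rng = np.random.default_rng(4)
        d = spiral_hemi.directions
        s = tensor_signal(d, 1000.0, [1.7e-3, 0.3e-3, 0.3e-3])
        s_noisy = s + rng.normal(scale=0.05, size=s.shape)
        train = np.ones(82, dtype=bool)
        train[::4] = False
        b_train = recon.sh_design_matrix(8, d[train])
        b_test = recon.sh_design_matrix(8, d[~train])
        mse = {}
        for lam in (0.0, 0.006):
            c = recon.fit_sh_regularized(s_noisy[train], b_train, lam)
            mse[lam] = np.mean((b_test.B @ c - s[~train]) ** 2)
        assert mse[0.006] <= mse[0.0]


class TestFunkRadon:
    def test_legendre_scaling_per_degree_block(self, spiral_hemi):
        basis = recon.sh_design_matrix(8, spiral_hemi.directions)
        c = np.ones(45)
        out = recon.qball_frt(c, basis)
        np.testing.assert_allclose(out[0], 2 * np.pi * 1.0)
        l2 = basis.degrees == 2
        np.testing.assert_allclose(out[l2], 2 * np.pi * (-0.5))
        l4 = basis.degrees == 4
        np.testing.assert_allclose(out[l4], 2 * np.pi * (3.0 / 8.0))

    def test_isotropic_signal_gives_constant_odf(self, spiral_hemi, sphere):
        basis = recon.sh_design_matrix(8, spiral_hemi.directions)
        s = np.full(82, 0.4)
        c = recon.fit_sh_regularized(s, basis)
        odf = recon.ODFField(recon.qball_frt(c, basis), 8)
        vals = recon.evaluate_odf(odf, sphere)
        assert np.ptp(vals) < 1e-6 * np.abs(vals).max()

    def test_single_fiber_odf_peaks_along_fiber(self, spiral_hemi, sphere):
        d = spiral_hemi.directions
        s = tensor_signal(d, 3000.0, [1.7e-3, 0.3e-3, 0.3e-3])  # fiber along x
        basis = recon.sh_design_matrix(8, d)
        c = recon.fit_sh_regularized(s, basis)
        odf = recon.ODFField(recon.qball_frt(c, basis), 8)
        vals = recon.evaluate_odf(odf, sphere)
        best = sphere.vertices[int(np.argmax(vals))]
        assert axis_angle_deg(best, np.array([1.0, 0, 0])) < 3.0

    def test_analytic_frt_matches_great_circle_quadrature(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(300, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        basis = recon.sh_design_matrix(8, d)
        # random but decaying coefficient sets, as real signals have
        c = rng.normal(size=45) / (1.0 + basis.degrees ** 2)
        analytic = recon.sh_design_matrix(8, d).B @ recon.qball_frt(c, basis)
        numeric = np.empty(d.shape[0])
        t = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
        for i, u in enumerate(d):
            helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e1 = np.cross(u, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            circle = np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2)
            f = recon.sh_design_matrix(8, circle).B @ c
            numeric[i] = f.mean() * 2 * np.pi
        rms = np.sqrt(np.mean((analytic - numeric) ** 2))
        assert rms / np.sqrt(np.mean(numeric ** 2)) < 0.02


class TestExtractPeaks:
    def test_constant_odf_has_no_peaks(self, sphere):
        odf = recon.ODFField(np.array([[1.0] + [0.0] * 44]), 8)
        peaks = recon.extract_peaks(odf, sphere)
        assert peaks.counts[0] == 0

    def test_orthogonal_crossing_recovered(self, spiral_hemi, sphere):
        d = spiral_hemi.directions
        s = 0.5 * tensor_signal(d, 3000.0, [1.7e-3, 0.3e-3, 0.3e-3])
        R = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
        s = s + 0.5 * tensor_signal(d, 3000.0, [1.7e-3, 0.3e-3, 0.3e-3],
                                    evecs=R)
        _, peaks = recon.qball_pipeline(s[None, :], d, sphere=sphere)
        assert peaks.counts[0] == 2
        for u in (np.array([1.0, 0, 0]), np.array([0.0, 1, 0])):
            best = min(axis_angle_deg(peaks.directions[0, i], u)
                       for i in range(2))
            assert best < 5.0

    def test_sub_threshold_peak_discarded(self, sphere):
        # three bumps, one at 4% of the maximum: only two survive the
        # 10% relative threshold
        v = sphere.vertices
        basis = sphere.basis(8)

        def bump(axis, amp):
            return amp * np.abs(v @ axis) ** 8

        target = (bump(np.array([1.0, 0, 0]), 1.0)
                  + bump(np.array([0.0, 1, 0]), 0.6)
                  + bump(np.array([0.0, 0, 1]), 0.04))
        c, *_ = np.linalg.lstsq(basis.B, target, rcond=None)
        peaks = recon.extract_peaks(recon.ODFField(c[None, :], 8), sphere)
        assert peaks.counts[0] == 2

    def test_min_separation_enforced(self, sphere):
        v = sphere.vertices
        basis = sphere.basis(8)
        target = np.abs(v @ np.array([1.0, 0, 0])) ** 8
        c, *_ = np.linalg.lstsq(basis.B, target, rcond=None)
        peaks = recon.extract_peaks(recon.ODFField(c[None, :], 8), sphere,
                                    min_separation=25.0)
        dirs = peaks.directions[0][: peaks.counts[0]]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                assert axis_angle_deg(dirs[i], dirs[j]) >= 25.0

    def test_rotation_equivariance(self, spiral_hemi, sphere):
        from scipy.spatial.transform import Rotation

        d = spiral_hemi.directions
        R = Rotation.from_euler("zyx", [33.0, 21.0, 10.0], degrees=True).as_matrix()
        fiber = np.array([1.0, 0.0, 0.0])
        s = tensor_signal(d, 3000.0, [1.7e-3, 0.3e-3, 0.3e-3])
        # rotating the gradient directions with the fiber leaves the
        # measured signal unchanged: peaks must rotate with the frame
        _, p1 = recon.qball_pipeline(s[None, :], d, sphere=sphere)
        _, p2 = recon.qball_pipeline(s[None, :], d @ R.T, sphere=sphere)
        a1 = p1.directions[0, 0]
        a2 = p2.directions[0, 0]
        assert axis_angle_deg(R @ a1, a2) < 5.0


class TestFitDTI:
    def make_volume(self, signals, scheme):
        data = np.concatenate([np.ones((*signals.shape[:-1], 1)), signals],
                              axis=-1)
        return DWIVolume(data.reshape(1, 1, -1, scheme.n + 1),
                         scheme.with_b0(1))

    def test_isotropic_signal(self, spiral_hemi):
        scheme = spiral_hemi.with_bvalue(1000.0)
        D = 1.0e-3
        s = np.exp(-1000.0 * D) * np.ones((1, 82))
        fit = recon.fit_dti(self.make_volume(s, scheme))
        assert fit.fa.ravel()[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.eigenvalues.ravel(), D, rtol=1e-8)

    def test_single_tensor_fa_closed_form(self, spiral_hemi):
        scheme = spiral_hemi.with_bvalue(1000.0)
        evals = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        s = tensor_signal(spiral_hemi.directions, 1000.0, evals)[None, :]
        fit = recon.fit_dti(self.make_volume(s, scheme))
        lam = evals
        fa_expected = np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2)
                              / np.sum(lam ** 2))
        assert fit.fa.ravel()[0] == pytest.approx(fa_expected, abs=1e-6)
        assert abs(fit.principal.reshape(3)[0]) > 0.999

    def test_noisy_isotropic_fa_stays_low(self, spiral_hemi):
        scheme = spiral_hemi.with_bvalue(1000.0)
        s = np.exp(-1000.0 * 1.0e-3) * np.ones((500, 82))
        vol = self.make_volume(s, scheme)
        noisy = phantom.add_rician_noise(vol, snr=40.0, seed=6)
        fit = recon.fit_dti(noisy)
        assert fit.fa.mean() < 0.15

    def test_requires_b0(self, spiral_hemi):
        vol = DWIVolume(np.ones((1, 1, 1, 82)), spiral_hemi.with_bvalue(1000.0))
        with pytest.raises(ValueError):
            recon.fit_dti(vol)
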