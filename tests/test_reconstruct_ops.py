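"""Elementary reconstruction operations against independent oracles.

The gradient tests validate the hand-derived Wirtinger backward pass by
central finite differences of the same objective: the data term with the
AP-updated spectrum held fixed at the base point (it is the projection
target, not a differentiated node) plus the TV terms that do carry
gradients.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fptycho as fp
from fptycho.fields import crop_window, fft2c, ifft2c
from fptycho.reconstruct import (_object_tv_backward, _vaiu_forward_backward,
                                 upsample_sqrt)


def dft2c(x: np.ndarray) -> np.ndarray:
    """Explicit DC-centered unitary DFT (oracle; no np.fft)."""
    n = x.shape[0]
    idx = np.arange(n) - n // 2
    w = np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)
    return w @ x @ w


def idft2c(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    idx = np.arange(n) - n // 2
    w = np.exp(2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)
    return w @ x @ w


class TestInitGuess:
    def test_sizes_and_zero_phase(self, small_stack, small_cfg):
        obj, pupil = fp.init_guess(small_stack, small_cfg)
        assert obj.size == small_cfg.upsample_factor * small_cfg.lowres_size
        assert np.all(obj.values.imag == 0.0)
        assert pupil.n_phase_params == 9
        assert np.all(pupil.coeffs.values == 0.0)
        assert np.array_equal(pupil.amplitude,
                              fp.make_ctf(small_cfg).values.real)

    def test_flat_center_image_gives_flat_unit_object(self, small_cfg,
                                                      zero_coeffs):
        flat = fp.make_phantom(small_cfg.highres_size, kind="flat")
        stack = fp.simulate_dataset(flat, zero_coeffs, small_cfg)
        obj, _ = fp.init_guess(stack, small_cfg)
        assert np.allclose(obj.values, 1.0, atol=1e-9)

    def test_missing_center_led_rejected(self, small_cfg):
        illum = fp.led_wave_vectors(small_cfg)
        off = fp.IlluminationSet(na_shifts=illum.na_shifts[1:],
                                 pixel_shifts=illum.pixel_shifts[1:],
                                 ordering=illum.ordering[1:])
        stack = fp.MeasurementStack(
            images=np.ones((off.n, small_cfg.lowres_size,
                            small_cfg.lowres_size)),
            illumination=off, config=small_cfg)
        with pytest.raises(ValueError, match="center"):
            fp.init_guess(stack, small_cfg)

    def test_sinc_upsampling_is_alignment_exact(self):
        # decimating the upsampled image recovers the original samples
        rng = np.random.default_rng(0)
        img = rng.random((8, 8)) + 0.5
        up = upsample_sqrt(img, 4)
        assert np.allclose(up[::4, ::4], np.sqrt(img), atol=1e-10)


class TestExtractAperture:
    def test_ideal_pupil_zero_shift_is_central_crop(self, small_cfg,
                                                    small_phantom):
        spec = fft2c(small_phantom.values)
        ctf = fp.make_ctf(small_cfg).values
        got = fp.extract_aperture(spec, ctf, (0, 0))
        n_hi, n_lo = small_cfg.highres_size, small_cfg.lowres_size
        lo = n_hi // 2 - n_lo // 2
        want = spec[lo:lo + n_lo, lo:lo + n_lo] * ctf
        assert np.array_equal(got, want)
        inside = np.abs(ctf) > 0
        assert np.array_equal(got[inside], spec[lo:lo + n_lo, lo:lo + n_lo][inside])

    def test_zero_pupil_gives_zero_field(self, small_phantom):
        spec = fft2c(small_phantom.values)
        got = fp.extract_aperture(spec, np.zeros((8, 8), complex), (2, -1))
        assert np.all(got == 0)

    def test_matches_index_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        spec = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        pupil = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        shift = (1, -2)
        got = fp.extract_aperture(spec, pupil, shift)
        want = np.empty((4, 4), complex)
        for i in range(4):
            for j in range(4):
                want[i, j] = spec[4 + shift[0] - 2 + i,
                                  4 + shift[1] - 2 + j] * pupil[i, j]
        assert np.allclose(got, want, rtol=0, atol=1e-12)

    def test_off_grid_rejected(self):
        spec = np.zeros((8, 8), complex)
        with pytest.raises(ValueError):
            fp.extract_aperture(spec, np.ones((4, 4), complex), (3, 0))


class TestApUpdate:
    def test_fixed_point(self):
        rng = np.random.default_rng(7)
        phi = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        measured = np.abs(ifft2c(phi)) ** 2
        assert np.allclose(fp.ap_update(phi, measured), phi, atol=1e-12)

    def test_zero_field_flat_measurement_gives_dc_delta(self):
        phi = np.zeros((4, 4), complex)
        out = fp.ap_update(phi, np.ones((4, 4)))
        spatial = ifft2c(out)
        assert np.allclose(spatial, 1.0, atol=1e-12)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(11)
        phi = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        measured = rng.random((4, 4))
        psi = idft2c(phi)
        want = dft2c(np.sqrt(measured) * psi / np.abs(psi))
        got = fp.ap_update(phi, measured)
        assert np.abs(got - want).max() < 1e-10

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        phi = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        measured = rng.random((6, 6))
        once = fp.ap_update(phi, measured)
        twice = fp.ap_update(once, measured)
        assert np.allclose(once, twice, atol=1e-10)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            fp.ap_update(np.zeros((4, 4), complex), -np.ones((4, 4)))


class TestTv:
    def test_constant_image_zero(self):
        assert fp.tv(np.full((5, 7), 3.2)) == 0.0

    def test_printed_2x2_example(self):
        # forward differences, zero at the last row/column:
        # sqrt(1+4) + sqrt(0+4) + sqrt(1+0) + 0
        assert fp.tv(np.array([[0.0, 1.0], [2.0, 3.0]]), eta=1.0) == \
            pytest.approx(np.sqrt(5) + 3.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneity_eta_one(self, seed, c):
        img = np.random.default_rng(seed).standard_normal((6, 6))
        assert fp.tv(c * img, 1.0) == pytest.approx(c * fp.tv(img, 1.0),
                                                    rel=1e-9)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        img = rng.standard_normal((6, 6))
        g = fp.tv_grad(img, eta=1.0)
        h = 1e-6
        for (i, j) in [(0, 0), (2, 3), (5, 5), (4, 0)]:
            plus, minus = img.copy(), img.copy()
            plus[i, j] += h
            minus[i, j] -= h
            fd = (fp.tv(plus) - fp.tv(minus)) / (2 * h)
            assert g[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestTotalLoss:
    def test_zero_when_identical_and_unregularized(self):
        rng = np.random.default_rng(17)
        phi = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        cfg = fp.ReconConfig(alpha1=0.0, alpha2=0.0)
        total, comp = fp.total_loss(phi, phi, cfg)
        assert total == 0.0 and comp["data"] == 0.0

    def test_reduces_to_data_term(self):
        rng = np.random.default_rng(19)
        a = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        b = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        cfg = fp.ReconConfig(alpha1=0.0, alpha2=0.0)
        total, comp = fp.total_loss(a, b, cfg)
        assert total == comp["data"] == pytest.approx(
            float(np.sum(np.abs(b - a) ** 2)))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(23)
        a = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        b = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        cfg = fp.ReconConfig(alpha1=0.7, alpha2=0.3)
        total, comp = fp.total_loss(a, b, cfg)
        spatial = idft2c(a)
        want = (np.sum(np.abs(b - a) ** 2)
                + 0.7 * fp.tv(np.abs(spatial))
                + 0.3 * fp.tv(np.angle(spatial)))
        assert total == pytest.approx(float(want), rel=1e-9)


class TestBackwardPass:
    """Central finite differences of the surrogate objective."""

    def _setup(self, alpha1=0.0, alpha2=0.0):
        cfg = fp.SystemConfig(led_rows=7, led_cols=7, lowres_size=16,
                              upsample_factor=2)
        basis = fp.basis_from_config(cfg, 6)
        rng = np.random.default_rng(29)
        n_hi, n_lo = cfg.highres_size, cfg.lowres_size
        O = rng.standard_normal((n_hi, n_hi)) + 1j * rng.standard_normal(
            (n_hi, n_hi))
        A = fp.make_ctf(cfg).values.real * rng.random((n_lo, n_lo))
        c = rng.normal(scale=0.5, size=6)
        s = rng.random((n_lo, n_lo)) + 0.1
        window = crop_window(O, (2, -3), n_lo)
        return basis, O, A, c, s, window, alpha1, alpha2

    def _surrogate(self, basis, O, A, c, s, window, alpha1, alpha2, phi_h0):
        """The objective whose exact gradient the backward pass returns."""
        theta = np.tensordot(c, basis.modes, axes=(0, 0))
        phi_l = O[window] * (A * np.exp(1j * theta))
        psi = ifft2c(phi_l)
        data = float(np.sum(np.abs(phi_l - phi_h0) ** 2))
        theta_s = np.where(s > 0, np.angle(psi), 0.0)
        return data + alpha1 * fp.tv(s) + alpha2 * fp.tv(theta_s)

    @pytest.mark.parametrize("alpha2", [0.0, 0.05])
    def test_gradients_match_finite_differences(self, alpha2):
        basis, O, A, c, s, window, a1, a2 = self._setup(alpha1=0.02,
                                                        alpha2=alpha2)
        comp, g_win, g_amp, g_coef = _vaiu_forward_backward(
            O, A, c, basis.modes, window, s, a1, a2, 1.0, True, True)
        # freeze the AP target at the base point
        theta = np.tensordot(c, basis.modes, axes=(0, 0))
        phi_l = O[window] * (A * np.exp(1j * theta))
        phi_h0 = fp.ap_update(phi_l, s ** 2)

        h = 1e-6
        rng = np.random.default_rng(31)
        rows = range(window[0].start, window[0].stop)
        cols = range(window[1].start, window[1].stop)
        # object spectrum: real and imaginary channels at random pixels
        for _ in range(4):
            i = rng.choice(list(rows))
            j = rng.choice(list(cols))
            for part, grad in ((1.0, g_win.real), (1.0j, g_win.imag)):
                Op, Om = O.copy(), O.copy()
                Op[i, j] += part * h
                Om[i, j] -= part * h
                fd = (self._surrogate(basis, Op, A, c, s, window, a1, a2, phi_h0)
                      - self._surrogate(basis, Om, A, c, s, window, a1, a2,
                                        phi_h0)) / (2 * h)
                wi, wj = i - window[0].start, j - window[1].start
                assert grad[wi, wj] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        # pupil amplitude at random in-disk pixels
        disk = np.argwhere(basis.mask)
        for i, j in disk[rng.choice(len(disk), 3, replace=False)]:
            Ap, Am = A.copy(), A.copy()
            Ap[i, j] += h
            Am[i, j] -= h
            fd = (self._surrogate(basis, O, Ap, c, s, window, a1, a2, phi_h0)
                  - self._surrogate(basis, O, Am, c, s, window, a1, a2,
                                    phi_h0)) / (2 * h)
            assert g_amp[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        # Zernike coefficients (piston gradient is pinned to zero)
        for l in range(1, 6):
            cp, cm = c.copy(), c.copy()
            cp[l] += h
            cm[l] -= h
            fd = (self._surrogate(basis, O, A, cp, s, window, a1, a2, phi_h0)
                  - self._surrogate(basis, O, A, cm, s, window, a1, a2,
                                    phi_h0)) / (2 * h)
            assert g_coef[l] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        assert g_coef[0] == 0.0

    def test_object_tv_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(37)
        n = 12
        O = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        a1, a2 = 0.3, 0.2

        def objective(Ox):
            o = ifft2c(Ox)
            return a1 * fp.tv(np.abs(o)) + a2 * fp.tv(np.angle(o))

        _, _, g = _object_tv_backward(O, a1, a2, 1.0, True)
        h = 1e-7
        for i, j in [(0, 0), (3, 7), (11, 5)]:
            for part, grad in ((1.0, g.real), (1.0j, g.imag)):
                Op, Om = O.copy(), O.copy()
                Op[i, j] += part * h
                Om[i, j] -= part * h
                fd = (objective(Op) - objective(Om)) / (2 * h)
                assert grad[i, j] == pytest.approx(fd, rel=1e-3, abs=1e-5)
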