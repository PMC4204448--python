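"""DoG preprocessing and E/I field dynamics: fixed points, closed forms, symmetry."""

import numpy as np
import pytest

from crowdbench.wilson_cowan import (
    DoGParams,
    IntegrationDivergedError,
    WCParams,
    WCState,
    _gauss_blur,
    lgn_preprocess,
    simulate,
    step,
)

SHAPE = (64, 64)


class TestDoG:
    def test_balanced_uniform_field_nulls(self):
        p = DoGParams(sigma_center=1.5, sigma_surround=4.0, balanced=True)
        out = lgn_preprocess(np.full(SHAPE, 0.37), p)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_single_pixel_matches_kernel(self):
        # the impulse response is the DoG kernel itself: positive centre,
        # negative annulus, evaluated directly as the oracle
        p = DoGParams(sigma_center=1.5, sigma_surround=4.0, balanced=True)
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = lgn_preprocess(img, p)

        y, x = np.mgrid[0:65, 0:65]
        r2 = (y - 32.0) ** 2 + (x - 32.0) ** 2

        def g(s):
            k = np.exp(-r2 / (2 * s * s))
            return k / k.sum()

        oracle = g(1.5) - g(4.0)
        np.testing.assert_allclose(out, oracle, atol=2e-5)
        assert out[32, 32] > 0
        assert out[32, 38] < 0  # annulus between centre and surround widths

    def test_dc_rejection(self, rng):
        p = DoGParams(balanced=True)
        x = rng.random(SHAPE)
        np.testing.assert_allclose(lgn_preprocess(x, p),
                                   lgn_preprocess(x + 0.25, p), atol=1e-8)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            DoGParams(sigma_center=5.0, sigma_surround=2.0)


class TestGaussBlur:
    def test_spectral_and_spatial_paths_agree(self, rng):
        # just above/below the implementation's path switch
        x = rng.normal(size=(128, 128))
        a = _gauss_blur(x, 12.0)
        from scipy.ndimage import gaussian_filter
        b = gaussian_filter(x, 12.0, mode="wrap")
        np.testing.assert_allclose(_gauss_blur(x, 12.001), b, atol=5e-3)
        assert np.allclose(a.sum(), x.sum(), atol=1e-6)


class TestStep:
    def test_zero_input_fixed_point(self):
        p = WCParams(duration=20.0)
        A = np.zeros(SHAPE)
        state = WCState.zeros(SHAPE)
        for _ in range(20):
            state = step(state, A, p)
        assert np.all(state.E == 0) and np.all(state.I == 0)

    def test_rectify_keeps_activity_nonnegative(self, rng):
        p = WCParams(w_IE=5.0)
        A = rng.normal(size=SHAPE)
        state = WCState.zeros(SHAPE)
        for _ in range(30):
            state = step(state, A, p)
            assert np.all(state.E >= 0) and np.all(state.I >= 0)

    def test_linear_limit_converges_to_blurred_drive(self, rng):
        # with couplings off and strictly positive drive, rectification is the
        # identity and E relaxes to G(sigma_E) * A: closed-form linear limit
        p = WCParams(sigma_E=2.0, sigma_I=4.0, w_EI=1e-12, w_IE=1e-12,
                     tau_E=10.0, dt=1.0)
        A = rng.random(SHAPE) + 1.0  # strictly positive, so G*A > 0
        from scipy.ndimage import gaussian_filter
        target = gaussian_filter(A, 2.0, mode="reflect")
        state = WCState.zeros(SHAPE)
        for _ in range(100):  # 10 * tau_E
            state = step(state, A, p)
        assert np.max(np.abs(state.E - target)) / np.max(np.abs(target)) < 0.01

    def test_step_size_refinement(self):
        # halving dt changes the terminal field by well under 2%
        from crowdbench.stimuli import StimulusGeometry, render_vernier
        g = StimulusGeometry(image_width_px=128, image_height_px=128, vernier_height=32)
        img = render_vernier(g, "right")
        dog = DoGParams()
        r1 = simulate(img, dog, WCParams(duration=60.0, dt=1.0))
        r2 = simulate(img, dog, WCParams(duration=60.0, dt=0.5))
        assert np.max(np.abs(r1 - r2)) / np.max(np.abs(r1)) < 0.02

    def test_divergence_detected_and_named(self):
        # activity large enough that one update overflows float range
        p = WCParams(w_EI=10.0)
        A = np.zeros(SHAPE)
        state = WCState(E=np.full(SHAPE, 1e308), I=np.zeros(SHAPE))
        with pytest.raises(IntegrationDivergedError, match="step"):
            for _ in range(5):
                state = step(state, A, p)

    def test_stability_guard(self):
        with pytest.raises(ValueError, match="stability"):
            WCParams(tau_E=10.0, tau_I=20.0, dt=5.0)


class TestSimulate:
    def test_mirror_equivariance(self):
        from crowdbench.stimuli import FlankerConfig, StimulusGeometry, add_flankers, render_vernier
        g = StimulusGeometry(image_width_px=128, image_height_px=128,
                             vernier_height=32, element_spacing=12)
        img = add_flankers(render_vernier(g, "right"), FlankerConfig("lines", 2, "equal"))
        dog, p = DoGParams(), WCParams(duration=40.0)
        resp = simulate(img, dog, p)
        resp_m = simulate(np.fliplr(img.pixels), dog, p, geometry=g)
        np.testing.assert_allclose(resp_m, np.fliplr(resp), atol=1e-10)

    def test_unflanked_vernier_drives_target_region(self):
        from crowdbench.stimuli import StimulusGeometry, render_vernier
        g = StimulusGeometry(image_width_px=128, image_height_px=128, vernier_height=32)
        resp = simulate(render_vernier(g, "right"), DoGParams(), WCParams(duration=60.0))
        assert np.max(np.abs(resp)) > 0
        centre = resp[48:80, 56:72]
        assert np.max(centre) == pytest.approx(np.max(resp))

    def test_determinism(self):
        from crowdbench.stimuli import StimulusGeometry, render_vernier
        g = StimulusGeometry(image_width_px=64, image_height_px=64, vernier_height=24)
        img = render_vernier(g, "left")
        a = simulate(img, DoGParams(), WCParams(duration=30.0))
        b = simulate(img, DoGParams(), WCParams(duration=30.0))
        assert np.array_equal(a, b)

    def test_sigmoid_transfer_bounded(self, rng):
        p = WCParams(transfer="sigmoid", duration=40.0)
        A = rng.normal(size=SHAPE) * 10
        resp = simulate(A, DoGParams(), p)
        assert np.all(resp >= 0) and np.all(resp <= 1)

    def test_time_average_readout(self):
        from crowdbench.stimuli import StimulusGeometry, render_vernier
        g = StimulusGeometry(image_width_px=64, image_height_px=64, vernier_height=24)
        img = render_vernier(g, "right")
        terminal = simulate(img, DoGParams(), WCParams(duration=40.0))
        averaged = simulate(img, DoGParams(), WCParams(duration=40.0, readout="time_average"))
        assert averaged.shape == terminal.shape
        assert not np.array_equal(averaged, terminal)
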