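"""Beer-Lambert renderer: scalar oracles, invariants, sRGB transfer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtualhe import (
    EncodingError,
    FluorescenceImage,
    RGBImage,
    RenderConfig,
    StainMatrix,
    dye_transmission,
    effective_contrast_ratio,
    render_beer_lambert,
    srgb_decode,
    srgb_encode,
)
from virtualhe.stain_model import srgb_forward, srgb_inverse

from conftest import single_pixel


class TestDyeTransmission:
    @pytest.mark.parametrize(
        "beta, intensity, expected",
        [
            (1.0, 0.0, 1.0),                      # no absorber: full transmission
            (0.0, 5.0, 1.0),                      # transparent dye
            (1.0, 1.0, math.exp(-2.5)),           # full-scale unit dye, k = 2.5
            (1.0, 100.0, 0.0075),                 # saturating input hits the floor
            (0.86, 1.0, math.exp(-0.86 * 2.5)),
        ],
    )
    def test_scalar_values(self, beta, intensity, expected):
        assert dye_transmission(beta, intensity) == pytest.approx(expected, rel=1e-12)

    def test_unity_iff_zero_absorption(self):
        assert dye_transmission(0.0, 0.7) == 1.0
        assert dye_transmission(0.3, 0.0) == 1.0
        assert dye_transmission(1e-6, 1e-6) < 1.0

    @pytest.mark.parametrize("beta, intensity", [(-0.1, 1.0), (1.0, -0.1)])
    def test_negative_inputs_rejected(self, beta, intensity):
        with pytest.raises(ValueError):
            dye_transmission(beta, intensity)

    def test_output_bounded_by_floor_and_one(self, rng):
        cfg = RenderConfig()
        t = dye_transmission(rng.uniform(0, 5, 100), rng.uniform(0, 5, 100), cfg)
        assert np.all(t >= cfg.floor) and np.all(t <= 1.0)


class TestRenderBeerLambert:
    def test_zero_input_renders_white(self, he_stains, linear_config):
        img = FluorescenceImage(np.zeros((4, 5, 2)), ["dapi", "eosin"])
        out = render_beer_lambert(img, he_stains, linear_config)
        assert out.encoding == "linear"
        np.testing.assert_array_equal(out.data, 1.0)
        encoded = render_beer_lambert(img, he_stains, RenderConfig())
        assert encoded.encoding == "srgb"
        np.testing.assert_array_equal(encoded.data, 1.0)

    def test_pure_hematoxylin_pixel(self, he_stains, linear_config):
        out = render_beer_lambert(single_pixel(1.0, 0.0), he_stains, linear_config)
        expected = np.exp(-2.5 * np.array([0.860, 1.000, 0.300]))
        np.testing.assert_allclose(out.data[0, 0], expected, rtol=1e-12)

    def test_multiplicativity_across_dyes(self, he_stains, linear_config):
        both = render_beer_lambert(single_pixel(1.0, 1.0), he_stains, linear_config)
        dapi_only = render_beer_lambert(single_pixel(1.0, 0.0), he_stains, linear_config)
        eosin_only = render_beer_lambert(single_pixel(0.0, 1.0), he_stains, linear_config)
        np.testing.assert_allclose(
            both.data, dapi_only.data * eosin_only.data, rtol=1e-12
        )

    def test_dye_order_irrelevant(self, random_image, he_stains, linear_config):
        flipped = StainMatrix(he_stains.beta[::-1], he_stains.dye_names[::-1])
        a = render_beer_lambert(random_image, he_stains, linear_config)
        b = render_beer_lambert(random_image, flipped, linear_config)
        np.testing.assert_array_equal(a.data, b.data)

    def test_label_mismatch_names_channels(self, he_stains):
        img = FluorescenceImage(np.zeros((2, 2, 2)), ["dapi", "rhodamine"])
        with pytest.raises(ValueError, match="rhodamine"):
            render_beer_lambert(img, he_stains)
        # positional fallback must be explicit
        out = render_beer_lambert(img, he_stains, match_by_position=True)
        assert out.shape == (2, 2, 3)

    def test_channel_count_mismatch(self, he_stains):
        img = FluorescenceImage(np.zeros((2, 2, 1)), ["dapi"])
        with pytest.raises(ValueError, match="1 channel"):
            render_beer_lambert(img, he_stains)

    def test_matches_scalar_per_pixel_oracle(self, random_image, he_stains, linear_config):
        """Whole-image vectorized renderer vs an independent math.exp loop."""
        out = render_beer_lambert(random_image, he_stains, linear_config)
        beta = {name: he_stains.row(name) for name in he_stains.dye_names}
        for i in range(random_image.shape[0]):
            for j in range(random_image.shape[1]):
                for m in range(3):
                    t = 1.0
                    for c, label in enumerate(random_image.channel_labels):
                        factor = math.exp(
                            -beta[label][m] * random_image.data[i, j, c] * linear_config.k
                        )
                        t *= max(factor, linear_config.floor)
                    assert abs(out.data[i, j, m] - t) <= 1e-9

    def test_monotone_decreasing_in_each_intensity(self, rng, he_stains, linear_config):
        base = rng.uniform(0, 0.8, size=(8, 8, 2))
        out0 = render_beer_lambert(
            FluorescenceImage(base, ["dapi", "eosin"]), he_stains, linear_config
        )
        for ch in range(2):
            bumped = base.copy()
            bumped[:, :, ch] += 0.1
            out1 = render_beer_lambert(
                FluorescenceImage(bumped, ["dapi", "eosin"]), he_stains, linear_config
            )
            assert np.all(out1.data <= out0.data + 1e-15)

    def test_never_below_floor_power_with_many_overlapping_dyes(self, linear_config):
        # five dyes all absorbing the same bands at saturating intensity
        n = 5
        stains = StainMatrix(np.ones((n, 3)), [f"dye{i}" for i in range(n)])
        img = FluorescenceImage(
            np.full((3, 3, n), 100.0), [f"dye{i}" for i in range(n)]
        )
        out = render_beer_lambert(img, stains, linear_config)
        assert np.all(out.data > 0)
        np.testing.assert_allclose(out.data, linear_config.floor**n, rtol=1e-12)


class TestSrgbTransfer:
    @pytest.mark.parametrize(
        "linear, encoded",
        [(0.0, 0.0), (1.0, 1.0), (0.0075, 0.08236), (0.002, 0.02584)],
    )
    def test_forward_values(self, linear, encoded):
        assert srgb_forward(linear) == pytest.approx(encoded, abs=5e-5)

    def test_round_trip_dense_grid(self):
        x = np.linspace(0.0, 1.0, 20001)
        np.testing.assert_allclose(srgb_inverse(srgb_forward(x)), x, atol=1e-9)
        y = RGBImage(np.stack([x[:10000].reshape(100, 100)] * 3, axis=2), "linear")
        np.testing.assert_allclose(
            srgb_decode(srgb_encode(y)).data, y.data, atol=1e-9
        )

    def test_matches_iec_literal(self, rng):
        """Cross-check against an independently coded IEC 61966-2-1 formula."""
        def iec(u):
            return 12.92 * u if u <= 0.0031308 else 1.055 * u ** (1 / 2.4) - 0.055

        for u in rng.uniform(0, 1, 200):
            assert srgb_forward(float(u)) == pytest.approx(iec(float(u)), abs=1e-12)

    def test_encoding_state_errors(self, rng):
        linear = RGBImage(rng.uniform(0, 1, (2, 2, 3)), "linear")
        encoded = srgb_encode(linear)
        with pytest.raises(EncodingError):
            srgb_encode(encoded)
        with pytest.raises(EncodingError):
            srgb_decode(linear)

    def test_monotone(self):
        x = np.linspace(0, 1, 4096)
        assert np.all(np.diff(srgb_forward(x)) > 0)


class TestEffectiveContrastRatio:
    def test_two_dye_default(self, he_stains):
        assert effective_contrast_ratio(he_stains) == pytest.approx(1376.0, abs=0.5)

    def test_single_dye(self):
        stains = StainMatrix([[0.86, 1.0, 0.3]], ["hematoxylin"])
        assert effective_contrast_ratio(stains) == pytest.approx(12.14, abs=0.01)

    def test_unity_floor_means_no_contrast(self, he_stains):
        # floor must lie strictly inside (0, 1); the limiting ratio at
        # floor -> 1 is exactly 1 (no attenuation possible)
        cfg = RenderConfig(floor=1.0 - 1e-12)
        assert effective_contrast_ratio(he_stains, cfg) == pytest.approx(1.0, abs=1e-6)

    def test_zero_floor_rejected(self, he_stains):
        with pytest.raises(ValueError):
            RenderConfig(floor=0.0)


class TestValidation:
    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            StainMatrix([[0.1, -0.2, 0.3]], ["bad"])

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            RenderConfig(k=0.0)
        with pytest.raises(ValueError):
            RenderConfig(floor=1.5)

    def test_fluorescence_invariants(self):
        with pytest.raises(ValueError):
            FluorescenceImage(np.full((2, 2, 1), -0.1), ["dapi"])
        with pytest.raises(ValueError):
            FluorescenceImage(np.zeros((2, 2, 2)), ["dapi", "dapi"])
        with pytest.raises(ValueError):
            FluorescenceImage(np.full((2, 2, 1), np.nan), ["dapi"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    dapi=st.floats(0.0, 10.0),
    eosin=st.floats(0.0, 10.0),
    k=st.floats(0.1, 5.0),
)
def test_output_range_property(dapi, eosin, k):
    """Any rendered value lies in [floor**D, 1] in linear light."""
    cfg = RenderConfig(k=k, apply_gamma=False)
    out = render_beer_lambert(single_pixel(dapi, eosin), config=cfg)
    assert np.all(out.data >= cfg.floor**2 - 1e-15)
    assert np.all(out.data <= 1.0)
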