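"""Additive color-mapping baselines for comparison with the Beer-Lambert renderer.

Earlier virtual-H&E displays treated each dye as self-luminous and built the
image by subtracting a weighted dye color from a backlight, optionally after
a nonlinear intensity transfer:

    out_M = clamp(backlight_M - sum_i color_{M,i} * I_i**gamma, 0, 1)

(gamma = 1 for the linear method). Where two dyes absorb the same band —
hematoxylin and eosin both absorb green strongly — the sum can exceed the
backlight and the channel clamps to zero, losing contrast; the multiplicative
Beer-Lambert model never does. These reimplementations are reconstructions
from the published description (backlight colors, clamping rule, the
existence of a nonlinear transfer), not ports of the original codes; the
transfer exponent is configurable rather than asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stain_model import StainMatrix, srgb_encode
from .types import FluorescenceImage, RGBImage

__all__ = [
    "AdditiveConfig",
    "render_additive_linear",
    "render_additive_nonlinear",
    "dynamic_range_report",
    "default_dye_colors",
]

# Backlight of the nonlinear method: slightly green-shifted white.
NONLINEAR_BACKLIGHT = (0.9, 1.0, 0.9)


def default_dye_colors(stains: StainMatrix | None = None) -> np.ndarray:
    """Subtractive color weights derived from the stain attenuation matrix.

    Each dye row is scaled so its strongest channel weight is 1: a single
    full-scale dye then spans the whole display range, keeping the additive
    renderings comparable to the Beer-Lambert one.
    """
    if stains is None:
        stains = StainMatrix.he_default()
    peak = stains.beta.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        colors = np.where(peak > 0, stains.beta / peak, 0.0)
    return colors


@dataclass
class AdditiveConfig:
    """Parameters of the additive baselines.

    dye_colors
        N x 3 nonnegative weights: how much of each display channel a
        full-scale dye subtracts from the backlight.
    dye_names
        Names matching the dye_colors rows; channels are matched by label.
    backlight
        Unattenuated display color; white for the linear method,
        (0.9, 1.0, 0.9) for the nonlinear method.
    transfer_exponent
        Power applied to intensities by the nonlinear method (default 0.5).
    apply_gamma
        sRGB-encode the output (default True, matching the main renderer).
    """

    dye_colors: np.ndarray = None
    dye_names: Optional[list] = None
    backlight: tuple = (1.0, 1.0, 1.0)
    transfer_exponent: float = 0.5
    apply_gamma: bool = True

    def __post_init__(self) -> None:
        if self.dye_colors is None:
            self.dye_colors = default_dye_colors()
            if self.dye_names is None:
                self.dye_names = ["dapi", "eosin"]
        self.dye_colors = np.atleast_2d(np.asarray(self.dye_colors, dtype=np.float64))
        if self.dye_colors.ndim != 2 or self.dye_colors.shape[1] != 3:
            raise ValueError(f"dye_colors must be N x 3, got {self.dye_colors.shape}")
        if np.any(self.dye_colors < 0) or not np.all(np.isfinite(self.dye_colors)):
            raise ValueError("dye_colors must be finite and >= 0")
        if self.dye_names is not None:
            self.dye_names = list(self.dye_names)
            if len(self.dye_names) != self.dye_colors.shape[0]:
                raise ValueError(
                    f"{len(self.dye_names)} dye names for "
                    f"{self.dye_colors.shape[0]} color rows"
                )
        self.backlight = tuple(float(b) for b in self.backlight)
        if len(self.backlight) != 3 or any(
            not (0.0 <= b <= 1.0) for b in self.backlight
        ):
            raise ValueError(f"backlight must be 3 values in [0, 1], got {self.backlight}")
        if not (np.isfinite(self.transfer_exponent) and self.transfer_exponent > 0):
            raise ValueError("transfer_exponent must be > 0")

    @classmethod
    def nonlinear_default(cls) -> "AdditiveConfig":
        return cls(backlight=NONLINEAR_BACKLIGHT)

    @property
    def n_dyes(self) -> int:
        return self.dye_colors.shape[0]


def _matched_colors(image: FluorescenceImage, config: AdditiveConfig) -> np.ndarray:
    if image.n_channels != config.n_dyes:
        raise ValueError(
            f"image has {image.n_channels} channels {image.channel_labels} "
            f"but additive config has {config.n_dyes} dye colors"
        )
    if config.dye_names is None:
        return config.dye_colors
    missing = sorted(set(image.channel_labels) ^ set(config.dye_names))
    if missing:
        raise ValueError(
            f"channel labels {list(image.channel_labels)} do not match dye "
            f"names {config.dye_names} (unmatched: {missing})"
        )
    order = [config.dye_names.index(lbl) for lbl in image.channel_labels]
    return config.dye_colors[order]


def _render_additive(
    image: FluorescenceImage, config: AdditiveConfig, exponent: float
) -> RGBImage:
    colors = _matched_colors(image, config)  # (N, 3)
    intensities = image.data if exponent == 1.0 else np.power(image.data, exponent)
    absorbed = np.tensordot(intensities, colors, axes=([2], [0]))  # (H, W, 3)
    linear = np.clip(np.asarray(config.backlight) - absorbed, 0.0, 1.0)
    out = RGBImage(linear, encoding="linear")
    if config.apply_gamma:
        out = srgb_encode(out)
    return out


def render_additive_linear(
    image: FluorescenceImage, config: AdditiveConfig | None = None
) -> RGBImage:
    """Additive baseline with a linear intensity transfer function.

    ``out = clamp(backlight - sum_i color_i * I_i, 0, 1)`` per channel;
    affine in the intensities until the clamp engages.
    """
    if config is None:
        config = AdditiveConfig()
    return _render_additive(image, config, exponent=1.0)


def render_additive_nonlinear(
    image: FluorescenceImage, config: AdditiveConfig | None = None
) -> RGBImage:
    """Additive baseline with a power-law intensity transfer function.

    As the linear method but with ``I_i**transfer_exponent`` and, by
    default, the green-shifted backlight (0.9, 1.0, 0.9).
    """
    if config is None:
        config = AdditiveConfig.nonlinear_default()
    return _render_additive(image, config, exponent=config.transfer_exponent)


def dynamic_range_report(
    rendered: RGBImage,
    reference: RGBImage,
    zero_input_mask: Optional[np.ndarray] = None,
) -> dict:
    """Quantify dynamic-range loss of a rendering against a reference.

    Reports per-channel min/max of the rendered image, the count of clamped
    pixels (any channel exactly 0 — the additive methods' failure mode; the
    Beer-Lambert model never produces them), and the white-point deviation:
    the maximum absolute difference from the reference, restricted to
    ``zero_input_mask`` (pixels with zero fluorescence input) when given.
    """
    if rendered.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: rendered {rendered.shape} vs reference {reference.shape}"
        )
    diff = np.abs(rendered.data - reference.data)
    if zero_input_mask is not None:
        zero_input_mask = np.asarray(zero_input_mask, dtype=bool)
        if zero_input_mask.shape != rendered.shape[:2]:
            raise ValueError(
                f"zero_input_mask shape {zero_input_mask.shape} does not match "
                f"image shape {rendered.shape[:2]}"
            )
        deviation = float(diff[zero_input_mask].max()) if zero_input_mask.any() else 0.0
    else:
        deviation = float(diff.max())
    clamped = np.any(rendered.data == 0.0, axis=2)
    return {
        "channel_min": [float(v) for v in rendered.data.min(axis=(0, 1))],
        "channel_max": [float(v) for v in rendered.data.max(axis=(0, 1))],
        "white_point_deviation": deviation,
        "clamped_pixel_count": int(clamped.sum()),
        "encoding": rendered.encoding,
    }
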