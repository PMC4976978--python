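"""Beer-Lambert virtual transillumination renderer.

Physical model
--------------
A transillumination microscope attenuates a white backlight exponentially in
the path-integrated dye concentration (the Beer-Lambert law). Because the
epi-fluorescence signal ``I_i`` of a dye is approximately linear in its
concentration, the virtual transmission of display channel M is

    T_M = prod_i  exp(-beta_{M,i} * I_i * k)

where ``beta_{M,i}`` is the attenuation of dye ``i`` integrated over the
spectral band of color channel M (the dye's "color" in the output space)
and ``k`` is a global scaling constant folding in detector gain.

Displays have finite contrast, so the per-absorber exponential is truncated
at a transmission floor (default 0.0075 of the peak display intensity).
Transmissions are computed in linear light; the standard two-segment sRGB
transfer is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .types import EncodingError, FluorescenceImage, RGBImage

__all__ = [
    "StainMatrix",
    "RenderConfig",
    "dye_transmission",
    "render_beer_lambert",
    "srgb_forward",
    "srgb_inverse",
    "srgb_encode",
    "srgb_decode",
    "effective_contrast_ratio",
    "HE_DEFAULT_BETA",
]

# Reference attenuation coefficients in sRGB, rows (R, G, B) per dye.
# Eosin absorbs green/blue (transmits pink); hematoxylin (measured via its
# fluorescent analog DAPI) absorbs red/green (transmits blue-purple).
HE_DEFAULT_BETA = {
    "eosin": (0.050, 1.000, 0.544),
    "hematoxylin": (0.860, 1.000, 0.300),
}

_SRGB_LINEAR_THRESHOLD = 0.0031308
_SRGB_ENCODED_THRESHOLD = 0.04045


@dataclass
class StainMatrix:
    """N dyes x 3 display channels of nonnegative attenuation coefficients.

    Row order follows ``dye_names``; column order is fixed (red, green, blue).
    """

    beta: np.ndarray
    dye_names: Sequence[str]

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=np.float64))
        self.dye_names = list(self.dye_names)
        if self.beta.ndim != 2 or self.beta.shape[1] != 3:
            raise ValueError(f"beta must be N x 3, got shape {self.beta.shape}")
        if self.beta.shape[0] < 1:
            raise ValueError("at least one dye is required")
        if len(self.dye_names) != self.beta.shape[0]:
            raise ValueError(
                f"{len(self.dye_names)} dye names for {self.beta.shape[0]} beta rows"
            )
        if len(set(self.dye_names)) != len(self.dye_names):
            raise ValueError(f"dye names not unique: {self.dye_names}")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta values must be finite")
        if np.any(self.beta < 0):
            raise ValueError("beta values must be >= 0")

    @property
    def n_dyes(self) -> int:
        return self.beta.shape[0]

    @classmethod
    def he_default(cls) -> "StainMatrix":
        """The reference hematoxylin & eosin stain matrix for sRGB.

        Channel labels follow the fluorophores: "dapi" is the nuclear
        (hematoxylin-analog) channel, "eosin" the cytoplasm/stroma channel.
        """
        return cls(
            beta=np.array(
                [HE_DEFAULT_BETA["hematoxylin"], HE_DEFAULT_BETA["eosin"]]
            ),
            dye_names=["dapi", "eosin"],
        )

    def row(self, dye: str) -> np.ndarray:
        try:
            return self.beta[self.dye_names.index(dye)]
        except ValueError:
            raise KeyError(f"no dye {dye!r}; have {self.dye_names}") from None


@dataclass
class RenderConfig:
    """Rendering constants.

    k
        Exponent scaling constant; a full-scale intensity of a dye with
        beta = 1 transmits exp(-k) ~ 8% before flooring. Default 2.5.
    floor
        Per-absorber transmission floor in (0, 1); default 0.0075 of peak
        display intensity.
    apply_gamma
        Apply the sRGB transfer after rendering (default True).
    """

    k: float = 2.5
    floor: float = 0.0075
    apply_gamma: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be a positive real, got {self.k}")
        if not (np.isfinite(self.floor) and 0 < self.floor < 1):
            raise ValueError(f"floor must lie in (0, 1), got {self.floor}")


ArrayLike = Union[float, np.ndarray]


def dye_transmission(
    beta: ArrayLike, intensity: ArrayLike, config: RenderConfig | None = None
) -> ArrayLike:
    """Transmission factor of a single absorbing dye.

    Returns ``max(exp(-beta * intensity * k), floor)``, elementwise for
    array input. Equals 1 exactly when ``beta * intensity == 0``.
    """
    if config is None:
        config = RenderConfig()
    beta_arr = np.asarray(beta, dtype=np.float64)
    inten = np.asarray(intensity, dtype=np.float64)
    if not (np.all(np.isfinite(beta_arr)) and np.all(np.isfinite(inten))):
        raise ValueError("beta and intensity must be finite")
    if np.any(beta_arr < 0):
        raise ValueError("beta must be >= 0")
    if np.any(inten < 0):
        raise ValueError("intensity must be >= 0")
    t = np.maximum(np.exp(-beta_arr * inten * config.k), config.floor)
    if t.ndim == 0:
        return float(t)
    return t


def _match_channels(
    image: FluorescenceImage, stains: StainMatrix, match_by_position: bool
) -> np.ndarray:
    """Return beta rows reordered to the image's channel order."""
    if image.n_channels != stains.n_dyes:
        raise ValueError(
            f"image has {image.n_channels} channels {image.channel_labels} "
            f"but stain matrix has {stains.n_dyes} dyes {stains.dye_names}"
        )
    if match_by_position:
        return stains.beta
    labels = list(image.channel_labels)
    names = list(stains.dye_names)
    missing = sorted(set(labels) ^ set(names))
    if missing:
        raise ValueError(
            f"channel labels {labels} do not match dye names {names} "
            f"(unmatched: {missing}); pass match_by_position=True to map "
            "channels to dyes positionally"
        )
    return np.stack([stains.row(lbl) for lbl in labels])


def render_beer_lambert(
    image: FluorescenceImage,
    stains: StainMatrix | None = None,
    config: RenderConfig | None = None,
    *,
    match_by_position: bool = False,
) -> RGBImage:
    """Render a virtual transillumination RGB image.

    Each display channel is the product over dyes of the per-dye,
    floor-clamped exponential transmission; zero input renders pure white
    backlight (1, 1, 1). Output is sRGB-encoded when ``config.apply_gamma``.
    """
    if stains is None:
        stains = StainMatrix.he_default()
    if config is None:
        config = RenderConfig()
    beta = _match_channels(image, stains, match_by_position)  # (N, 3)

    # (H, W, N, 1) * (N, 3) -> per-dye, per-channel transmissions (H, W, N, 3)
    optical_density = config.k * image.data[..., np.newaxis] * beta[np.newaxis, np.newaxis]
    per_dye = np.maximum(np.exp(-optical_density), config.floor)
    linear = per_dye.prod(axis=2)
    out = RGBImage(linear, encoding="linear")
    if config.apply_gamma:
        out = srgb_encode(out)
    return out


def srgb_forward(x: ArrayLike) -> ArrayLike:
    """Standard sRGB forward transfer (linear light -> encoded value).

    Linear segment (slope 12.92) below 0.0031308, offset power segment
    (exponent 1/2.4) above. Maps [0, 1] onto [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    lo = 12.92 * x
    hi = 1.055 * np.power(np.maximum(x, _SRGB_LINEAR_THRESHOLD), 1.0 / 2.4) - 0.055
    y = np.where(x <= _SRGB_LINEAR_THRESHOLD, lo, hi)
    y = np.where(x >= 1.0, 1.0, y)  # keep the white point exact
    if y.ndim == 0:
        return float(y)
    return y


def srgb_inverse(y: ArrayLike) -> ArrayLike:
    """Inverse sRGB transfer (encoded value -> linear light)."""
    y = np.asarray(y, dtype=np.float64)
    lo = y / 12.92
    hi = np.power((np.maximum(y, _SRGB_ENCODED_THRESHOLD) + 0.055) / 1.055, 2.4)
    x = np.where(y <= _SRGB_ENCODED_THRESHOLD, lo, hi)
    x = np.where(y >= 1.0, 1.0, x)
    if x.ndim == 0:
        return float(x)
    return x


def srgb_encode(image: RGBImage) -> RGBImage:
    """Apply the sRGB transfer to a linear-light image."""
    image.require_encoding("linear", "srgb_encode")
    return RGBImage(np.clip(srgb_forward(image.data), 0.0, 1.0), encoding="srgb")


def srgb_decode(image: RGBImage) -> RGBImage:
    """Invert the sRGB transfer, returning linear light."""
    image.require_encoding("srgb", "srgb_decode")
    return RGBImage(np.clip(srgb_inverse(image.data), 0.0, 1.0), encoding="linear")


def effective_contrast_ratio(
    stains: StainMatrix | None = None, config: RenderConfig | None = None
) -> float:
    """Displayed contrast between white and the darkest achievable channel.

    With D dyes each clamped at the transmission floor, a channel can reach
    floor**D in linear light; the ratio reported is
    ``srgb_forward(1.0) / srgb_forward(floor**D)``. For the default two-dye
    H&E configuration this is ~1376, i.e. the model assumes a display
    contrast of roughly 1000:1.
    """
    if stains is None:
        stains = StainMatrix.he_default()
    if config is None:
        config = RenderConfig()
    if config.floor <= 0:
        raise ValueError("floor must be > 0 (zero floor gives infinite contrast)")
    darkest = config.floor ** stains.n_dyes
    return float(srgb_forward(1.0) / srgb_forward(darkest))
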