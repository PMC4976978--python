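"""Shared domain containers for fluorescence input and rendered RGB output.

A :class:`FluorescenceImage` holds the per-fluorophore intensity fields
``I_i`` (dimensionless, full scale = 1.0) that drive every renderer; an
:class:`RGBImage` holds a virtual transmission image, tagged as linear light
or sRGB-encoded so that the gamma transfer can never be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["FluorescenceImage", "RGBImage", "EncodingError"]


class EncodingError(ValueError):
    """Raised when an operation receives an RGB image in the wrong encoding."""


@dataclass
class FluorescenceImage:
    """H x W x N stack of normalized fluorophore intensities.

    Parameters
    ----------
    data
        Array of shape (H, W, N) with finite, nonnegative intensities.
        Full scale is 1.0 by convention; auto-gain produces values <= 1.
    channel_labels
        N unique dye names, e.g. ``["dapi", "eosin"]``. Renderers match
        channels to stain rows by these labels, never silently by position.
    pixel_size_um
        Optional physical pixel pitch in micrometres.
    """

    data: np.ndarray
    channel_labels: Sequence[str]
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[:, :, np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(
                f"fluorescence data must be H x W x N, got shape {self.data.shape}"
            )
        self.channel_labels = list(self.channel_labels)
        n = self.data.shape[2]
        if n < 1:
            raise ValueError("at least one fluorophore channel is required")
        if len(self.channel_labels) != n:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError(f"channel labels not unique: {self.channel_labels}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fluorescence intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("fluorescence intensities must be >= 0")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def channel(self, label: str) -> np.ndarray:
        """Return the 2-D intensity plane for one dye, by name."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.data[:, :, idx]


@dataclass
class RGBImage:
    """H x W x 3 virtual transmission image with values in [0, 1].

    ``encoding`` is ``"linear"`` for linear-light transmissions straight out
    of a renderer and ``"srgb"`` after the display transfer function.
    """

    data: np.ndarray
    encoding: str = "linear"

    _ENCODINGS = ("linear", "srgb")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"RGB data must be H x W x 3, got {self.data.shape}")
        if self.encoding not in self._ENCODINGS:
            raise ValueError(f"encoding must be one of {self._ENCODINGS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RGB values must be finite")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("RGB values must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def require_encoding(self, encoding: str, op: str) -> None:
        if self.encoding != encoding:
            raise EncodingError(
                f"{op} requires a {encoding}-encoded image, got {self.encoding}"
            )
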