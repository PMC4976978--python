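"""Per-channel histogram auto-gain.

Each fluorescence channel is rescaled so that a fixed tiny fraction of its
pixels — one per 100,000 by default — sits at full scale, standardizing
stain intensity across acquisitions the way a histology lab standardizes
dye concentrations. The gain is a rank statistic: the pivot is the r-th
largest value of the channel with r = max(1, floor(N * saturation_fraction)),
and gain = 1 / pivot. Pixels >= pivot saturate (ties at the pivot all
saturate), so the map is deterministic, monotone and idempotent: once the
quota of saturated pixels exists, the pivot is full scale and the gain is 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import FluorescenceImage

__all__ = ["GainResult", "autogain_channel", "normalize_frame", "normalize_stack"]

logger = logging.getLogger(__name__)

FULL_SCALE = 1.0
DEFAULT_SATURATION_FRACTION = 1e-5


@dataclass
class GainResult:
    """Outcome of auto-gaining one channel."""

    gain: float
    pivot_value: float
    n_saturated_before: int
    n_saturated_after: int
    channel: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "gain": self.gain,
            "pivot_value": self.pivot_value,
            "n_saturated_before": self.n_saturated_before,
            "n_saturated_after": self.n_saturated_after,
        }


def _pivot(values: np.ndarray, saturation_fraction: float) -> Tuple[float, int]:
    n = values.size
    r = max(1, math.floor(n * saturation_fraction))
    # r-th largest value via partial sort
    pivot = float(np.partition(values, n - r)[n - r])
    return pivot, r


def autogain_channel(
    channel: np.ndarray,
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION,
    label: Optional[str] = None,
) -> Tuple[np.ndarray, GainResult]:
    """Rescale one intensity channel so ~saturation_fraction of pixels saturate.

    Parameters
    ----------
    channel
        Nonempty array of finite, nonnegative intensities (any shape).
    saturation_fraction
        Target saturated fraction in (0, 1); default 1e-5 (one per 100,000).
    label
        Channel name recorded in the :class:`GainResult` and error messages.

    Returns
    -------
    (scaled, result)
        ``scaled = min(channel * gain, 1.0)`` and the gain bookkeeping.
    """
    name = f"channel {label!r}" if label else "channel"
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not (0.0 < saturation_fraction < 1.0):
        raise ValueError(
            f"saturation_fraction must lie in (0, 1), got {saturation_fraction}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative values")
    flat = arr.ravel()
    if not np.any(flat > 0):
        raise ValueError(f"{name} is all zero; auto-gain is undefined")
    if flat.min() == flat.max():
        logger.warning(
            "%s is constant (%g); auto-gain saturates every pixel", name, flat[0]
        )

    n_sat_before = int(np.count_nonzero(flat >= FULL_SCALE))
    pivot, _ = _pivot(flat, saturation_fraction)
    gain = FULL_SCALE / pivot
    if gain < 1.0:
        logger.warning(
            "%s over-exposed (pivot %.4g > full scale); applying gain %.4g < 1",
            name,
            pivot,
            gain,
        )
    # pixels >= pivot saturate by definition (ties included); applying the
    # mask explicitly keeps the rule exact under floating-point rounding
    scaled = np.where(arr >= pivot, FULL_SCALE, np.minimum(arr * gain, FULL_SCALE))
    n_sat_after = int(np.count_nonzero(scaled >= FULL_SCALE))
    return scaled, GainResult(
        gain=float(gain),
        pivot_value=pivot,
        n_saturated_before=n_sat_before,
        n_saturated_after=n_sat_after,
        channel=label,
    )


def normalize_frame(
    image: FluorescenceImage,
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION,
) -> Tuple[FluorescenceImage, List[GainResult]]:
    """Auto-gain every fluorophore channel of an image independently."""
    channels = []
    results = []
    for i, label in enumerate(image.channel_labels):
        scaled, res = autogain_channel(
            image.data[:, :, i], saturation_fraction, label=label
        )
        channels.append(scaled)
        results.append(res)
    out = FluorescenceImage(
        np.stack(channels, axis=2),
        channel_labels=list(image.channel_labels),
        pixel_size_um=image.pixel_size_um,
    )
    return out, results


def normalize_stack(
    images: Sequence[FluorescenceImage],
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION,
) -> Tuple[List[FluorescenceImage], List[GainResult]]:
    """Auto-gain a multi-field acquisition with one gain per channel.

    The pivot is computed on the pooled histogram of each channel across all
    fields of the mosaic, then the same gain is applied to every field, so
    adjacent fields stay mutually consistent after stitching.
    """
    if not images:
        raise ValueError("no images supplied")
    labels = list(images[0].channel_labels)
    for img in images[1:]:
        if list(img.channel_labels) != labels:
            raise ValueError(
                f"inconsistent channel labels across fields: {labels} vs "
                f"{list(img.channel_labels)}"
            )
    gains: List[GainResult] = []
    scaled_channels: List[List[np.ndarray]] = [[] for _ in images]
    for i, label in enumerate(labels):
        pooled = np.concatenate([img.data[:, :, i].ravel() for img in images])
        _, res = autogain_channel(pooled, saturation_fraction, label=label)
        gains.append(res)
        for j, img in enumerate(images):
            chan = img.data[:, :, i]
            scaled_channels[j].append(
                np.where(
                    chan >= res.pivot_value,
                    FULL_SCALE,
                    np.minimum(chan * res.gain, FULL_SCALE),
                )
            )
    out = [
        FluorescenceImage(
            np.stack(chans, axis=2),
            channel_labels=labels,
            pixel_size_um=img.pixel_size_um,
        )
        for chans, img in zip(scaled_channels, images)
    ]
    return out, gains
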