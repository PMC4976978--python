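"""Readers and writers for fluorescence TIFFs, RGB output and stain configs.

Grayscale 8/16-bit TIFF pages map linearly onto [0, 1] (by 1/255 or
1/65535); RGB output is quantized to 8 bits only at write time, after sRGB
encoding, so the files round-trip exactly at 8-bit precision. Stain
parameters travel as a small JSON object; the bundled ``he_default.json``
carries the reference H&E attenuation coefficients.
"""

from __future__ import annotations

import json
import os
import tempfile
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .baselines import AdditiveConfig, default_dye_colors
from .stain_model import RenderConfig, StainMatrix
from .types import FluorescenceImage, RGBImage

__all__ = [
    "read_fluorescence",
    "write_rgb",
    "write_fluorescence",
    "load_stain_config",
    "load_additive_config",
    "default_stain_config_path",
]

_SCALE = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def default_stain_config_path() -> Path:
    """Path of the bundled reference H&E stain configuration."""
    return Path(resources.files("virtualhe").joinpath("data/he_default.json"))


def _read_pages(source) -> List[np.ndarray]:
    if isinstance(source, (str, Path)):
        try:
            arr = tifffile.imread(source)
        except (OSError, tifffile.TiffFileError) as exc:
            raise ValueError(f"cannot read {source}: {exc}") from exc
        # multi-page stacks come back as (N, H, W); split into planes
        return list(arr) if arr.ndim == 3 else [arr]
    pages = []
    for path in source:
        try:
            arr = tifffile.imread(path)
        except (OSError, tifffile.TiffFileError) as exc:
            raise ValueError(f"cannot read {path}: {exc}") from exc
        if arr.ndim == 3:
            pages.extend(arr)
        else:
            pages.append(arr)
    return pages


def read_fluorescence(
    source: Union[str, Path, Sequence[Union[str, Path]]],
    channel_labels: Sequence[str],
    pixel_size_um: Optional[float] = None,
) -> FluorescenceImage:
    """Read a multichannel fluorescence image from grayscale TIFF(s).

    ``source`` is either one multi-page TIFF or a sequence of single-page
    files, one page per fluorophore in ``channel_labels`` order. 8-bit
    values are scaled by 1/255 and 16-bit by 1/65535 into [0, 1].
    """
    pages = _read_pages(source)
    if len(pages) != len(channel_labels):
        raise ValueError(
            f"{len(pages)} image pages for {len(channel_labels)} channel "
            f"labels {list(channel_labels)}"
        )
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent page dimensions: {sorted(shapes)}")
    dtypes = {p.dtype for p in pages}
    if len(dtypes) > 1:
        raise ValueError(f"inconsistent page bit depths: {sorted(map(str, dtypes))}")
    (dtype,) = dtypes
    if dtype not in _SCALE:
        raise ValueError(f"unsupported bit depth {dtype}; expected uint8 or uint16")
    if any(p.ndim != 2 for p in pages):
        raise ValueError("each page must be a 2-D grayscale image")
    data = np.stack([p.astype(np.float64) / _SCALE[dtype] for p in pages], axis=2)
    return FluorescenceImage(data, channel_labels=channel_labels, pixel_size_um=pixel_size_um)


def _atomic_write(path: Path, writer) -> None:
    """Write via a sibling temp file so failures leave no partial output."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_rgb(
    image: RGBImage,
    path: Union[str, Path],
    format: Optional[str] = None,
    *,
    convert_linear: bool = False,
) -> None:
    """Write an sRGB-encoded image as 8-bit PNG or TIFF.

    Values are quantized by ``round(v * 255)``. Linear-light input is
    refused unless ``convert_linear=True`` applies the sRGB transfer first.
    """
    from .stain_model import srgb_encode

    if image.encoding == "linear":
        if not convert_linear:
            raise ValueError(
                "refusing to write linear-light data; pass convert_linear=True "
                "to sRGB-encode on write"
            )
        image = srgb_encode(image)
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("tif", "tiff"):
        fmt = "tiff"
    elif fmt != "png":
        raise ValueError(f"unsupported output format {fmt!r}; use png or tiff")
    quantized = np.round(image.data * 255.0).astype(np.uint8)
    if fmt == "tiff":
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, quantized, photometric="rgb"))
    else:
        _atomic_write(path, lambda tmp: iio.imwrite(tmp, quantized, extension=".png"))


def write_fluorescence(image: FluorescenceImage, path: Union[str, Path]) -> None:
    """Write a fluorescence image as a multi-page 16-bit grayscale TIFF."""
    path = Path(path)
    pages = np.moveaxis(np.round(image.data * 65535.0).astype(np.uint16), 2, 0)
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, pages))


def _load_json(path: Union[str, Path]) -> dict:
    try:
        with open(path) as fh:
            cfg = json.load(fh)
    except OSError as exc:
        raise ValueError(f"cannot read stain config {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"stain config {path} must be a JSON object")
    return cfg


def load_stain_config(
    path: Union[str, Path, None] = None,
) -> Tuple[StainMatrix, RenderConfig]:
    """Load a stain matrix and render constants from JSON.

    Schema: ``{"dyes": [{"name", "beta": [r, g, b]}, ...], "k", "floor"}``;
    missing ``k``/``floor`` take the defaults 2.5 / 0.0075. ``path=None``
    loads the bundled reference H&E configuration.
    """
    if path is None:
        path = default_stain_config_path()
    cfg = _load_json(path)
    dyes = cfg.get("dyes")
    if not isinstance(dyes, list) or not dyes:
        raise ValueError(f"stain config {path} must list at least one dye")
    names, beta_rows = [], []
    for entry in dyes:
        name = entry.get("name") if isinstance(entry, dict) else None
        beta = entry.get("beta") if isinstance(entry, dict) else None
        if not name:
            raise ValueError(f"dye entry missing a name in {path}: {entry!r}")
        if not (isinstance(beta, (list, tuple)) and len(beta) == 3):
            raise ValueError(f"dye {name!r} needs a 3-element beta list in {path}")
        names.append(str(name))
        beta_rows.append([float(b) for b in beta])
    stains = StainMatrix(beta=np.array(beta_rows), dye_names=names)
    render = RenderConfig(
        k=float(cfg.get("k", 2.5)),
        floor=float(cfg.get("floor", 0.0075)),
        apply_gamma=bool(cfg.get("apply_gamma", True)),
    )
    return stains, render


def load_additive_config(
    path: Union[str, Path, None] = None, method: str = "additive_linear"
) -> AdditiveConfig:
    """Load one additive baseline's parameters from the same JSON family.

    Reads the ``"additive_linear"`` or ``"additive_nonlinear"`` section;
    dye colors default to the stain matrix's rows scaled to unit peak.
    """
    if method not in ("additive_linear", "additive_nonlinear"):
        raise ValueError(f"unknown additive method {method!r}")
    if path is None:
        path = default_stain_config_path()
    cfg = _load_json(path)
    stains, _ = load_stain_config(path)
    section = cfg.get(method, {})
    if not isinstance(section, dict):
        raise ValueError(f"section {method!r} in {path} must be a JSON object")
    default_backlight = (1.0, 1.0, 1.0) if method == "additive_linear" else (0.9, 1.0, 0.9)
    colors = section.get("dye_colors")
    return AdditiveConfig(
        dye_colors=np.array(colors, dtype=float) if colors is not None else default_dye_colors(stains),
        dye_names=list(stains.dye_names),
        backlight=tuple(section.get("backlight", default_backlight)),
        transfer_exponent=float(section.get("transfer_exponent", 0.5)),
    )
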