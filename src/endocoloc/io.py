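"""Reading and writing multi-channel micrographs and result tables.

The package works on three co-registered fluorescence channels with fixed
roles: ``probe`` (integrin-targeting AIE-cRGD probe), ``pfak``
(phospho-FAK immunostain) and ``rab5`` (early-endosome marker).  Images
travel either as multi-page TIFF (one page per channel, uint8/uint16) or as
8-bit RGB PNG under the pseudo-color convention blue = probe, red = pFAK,
green = Rab5.  A JSON sidecar records the declared bit depth — in
particular 12-bit confocal data stored in a 16-bit container — and a
free-text provenance label.

Coordinates are (row, col), 0-based, row 0 at the top, throughout the
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ROLES",
    "DEFAULT_RGB_MAP",
    "DEFAULT_TIFF_MAP",
    "MultiChannelImage",
    "read_image",
    "write_image",
    "write_pixel_table",
    "read_pixel_table",
]

#: Channel roles, in canonical storage order.
ROLES = ("probe", "pfak", "rab5")

#: Pseudo-color convention for RGB files: blue = probe, red = pFAK,
#: green = Rab5.
DEFAULT_RGB_MAP = {"probe": 2, "pfak": 0, "rab5": 1}

#: Page order for multi-page TIFFs written by this package.
DEFAULT_TIFF_MAP = {"probe": 0, "pfak": 1, "rab5": 2}

_ALLOWED_DEPTHS = (8, 12, 16)


@dataclass
class MultiChannelImage:
    """A fixed-size grid of three co-registered integer intensity channels.

    Parameters
    ----------
    probe, pfak, rab5
        2D non-negative integer arrays of identical shape, one per channel
        role.
    bit_depth
        Declared intensity depth (8, 12 or 16); every intensity must lie in
        ``[0, 2**bit_depth - 1]``.
    source_id
        Free-text provenance label carried into result tables.
    """

    probe: np.ndarray
    pfak: np.ndarray
    rab5: np.ndarray
    bit_depth: int = 16
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_ALLOWED_DEPTHS}, got {self.bit_depth}")
        arrays = {}
        for role in ROLES:
            arr = np.asarray(getattr(self, role))
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} must be 2D, got shape {arr.shape}")
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"channel {role!r} must have integer dtype, got {arr.dtype}")
            arrays[role] = arr
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        limit = self.max_intensity
        for role, arr in arrays.items():
            if arr.size and (int(arr.min()) < 0 or int(arr.max()) > limit):
                raise ValueError(
                    f"channel {role!r} has intensities outside [0, {limit}] "
                    f"for bit_depth {self.bit_depth}"
                )
            setattr(self, role, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probe.shape

    @property
    def height(self) -> int:
        return self.probe.shape[0]

    @property
    def width(self) -> int:
        return self.probe.shape[1]

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    def channel(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise KeyError(f"unknown channel role {role!r}; expected one of {ROLES}")
        return getattr(self, role)

    def stack(self) -> np.ndarray:
        """Channels stacked in canonical (probe, pfak, rab5) order, shape (3, H, W)."""
        return np.stack([self.probe, self.pfak, self.rab5])

    def with_source_id(self, source_id: str) -> "MultiChannelImage":
        return replace(self, source_id=source_id)


def _check_channel_map(channel_map: Mapping[str, int], n_channels: int) -> dict[str, int]:
    cmap = dict(channel_map)
    if set(cmap) != set(ROLES):
        raise ValueError(f"channel_map must cover exactly the roles {ROLES}, got {sorted(cmap)}")
    indices = list(cmap.values())
    if len(set(indices)) != len(indices):
        raise ValueError(f"channel_map indices must be distinct, got {indices}")
    for role, idx in cmap.items():
        if not 0 <= idx < n_channels:
            raise ValueError(
                f"channel index out of range: role {role!r} maps to index {idx} "
                f"but the file has {n_channels} channel(s)"
            )
    return cmap


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_image(path: str | Path, channel_map: Mapping[str, int] | None = None) -> MultiChannelImage:
    """Read a multi-page TIFF or RGB PNG into a :class:`MultiChannelImage`.

    Raw integer intensities are preserved exactly — no rescaling, no gamma.
    ``channel_map`` assigns each role to a page index (TIFF) or color plane
    index (PNG, 0=R 1=G 2=B); defaults follow the package conventions
    (:data:`DEFAULT_TIFF_MAP`, :data:`DEFAULT_RGB_MAP`).  A JSON sidecar
    next to the file, if present, supplies ``bit_depth`` and ``source_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a multi-page TIFF of 2D pages, got shape {data.shape}")
        planes = data  # (pages, H, W)
        default_map = DEFAULT_TIFF_MAP
    elif suffix == ".png":
        rgb = iio.imread(path)
        if rgb.ndim != 3:
            raise ValueError(f"expected an RGB PNG, got array of shape {rgb.shape}")
        planes = np.moveaxis(rgb, -1, 0)  # (channels, H, W)
        default_map = DEFAULT_RGB_MAP
    else:
        raise ValueError(f"unsupported image format {suffix!r}; use .tif/.tiff or .png")

    if not np.issubdtype(planes.dtype, np.integer):
        raise ValueError(f"non-integer sample format {planes.dtype}; raw integer intensities required")

    cmap = _check_channel_map(channel_map or default_map, planes.shape[0])

    bit_depth = 16 if planes.dtype.itemsize > 1 else 8
    source_id = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bit_depth = int(meta.get("bit_depth", bit_depth))
        source_id = str(meta.get("source_id", source_id))

    channels = {role: planes[idx].copy() for role, idx in cmap.items()}
    return MultiChannelImage(bit_depth=bit_depth, source_id=source_id, **channels)


def write_image(img: MultiChannelImage, path: str | Path) -> Path:
    """Write ``img`` so that :func:`read_image` reproduces it bit-exactly.

    TIFF output stacks one page per channel in canonical role order; PNG
    output (8-bit only) uses the pseudo-color convention.  A JSON sidecar
    always records ``bit_depth`` and ``source_id`` — this is how 12-bit
    data survive the 16-bit TIFF container.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        dtype = np.uint8 if img.bit_depth == 8 else np.uint16
        pages = np.empty((3,) + img.shape, dtype=dtype)
        for role, idx in DEFAULT_TIFF_MAP.items():
            pages[idx] = img.channel(role)
        tifffile.imwrite(path, pages, photometric="minisblack")
    elif suffix == ".png":
        if img.bit_depth != 8:
            raise ValueError("PNG output supports bit_depth 8 only; use TIFF for deeper data")
        rgb = np.zeros(img.shape + (3,), dtype=np.uint8)
        for role, idx in DEFAULT_RGB_MAP.items():
            rgb[..., idx] = img.channel(role)
        iio.imwrite(path, rgb)
    else:
        raise ValueError(f"unsupported image format {suffix!r}; use .tif/.tiff or .png")

    meta = {"bit_depth": img.bit_depth, "source_id": img.source_id}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def write_pixel_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> Path:
    """Write per-pixel or per-island records as a headed CSV, numbers unrounded.

    ``rows`` may be a DataFrame or a sequence of records sharing a schema;
    an empty sequence needs a DataFrame (or raises) because the header
    cannot be inferred from nothing.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("empty record list with no schema; pass a DataFrame with columns instead")
        frame = pd.DataFrame(rows)
    if frame.shape[1] == 0:
        raise ValueError("record schema is empty: no columns to write")
    frame.to_csv(path, index=False)
    return path


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_pixel_table`."""
    return pd.read_csv(path)
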