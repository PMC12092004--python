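"""Multichannel field, ROI label-mask and vesicle-table input/output.

Images are single-plane confocal fields stored as TIFF/OME-TIFF.  A field
carries one 2-D intensity grid per channel plus a mapping from semantic
channel roles (eGFP-LC3, mRFP-LC3, CTSD immunolabel, optional IR and
nuclear channels) to channel indices.  Vesicle classification requires
the three reporter roles GFP_LC3, RFP_LC3 and CTSD to be bound.

Coordinate convention: row-major, 0-based pixel indices; pixel centres at
integer coordinates.  Native integer intensities are preserved through
segmentation; normalisation to [0, 1] happens only where lightness is
needed (see :mod:`avhue.classify`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class ChannelRole(str, enum.Enum):
    """Semantic identity of an acquisition channel."""

    GFP_LC3 = "GFP_LC3"
    RFP_LC3 = "RFP_LC3"
    CTSD = "CTSD"
    IR = "IR"
    NUCLEAR = "NUCLEAR"


#: Roles that must be bound before hue-angle classification can run.
CLASSIFICATION_ROLES = (ChannelRole.GFP_LC3, ChannelRole.RFP_LC3, ChannelRole.CTSD)


class MaskKind(str, enum.Enum):
    PERIKARYON = "PERIKARYON"
    WHOLE_CELL = "WHOLE_CELL"
    FIELD = "FIELD"


def _as_role(key: ChannelRole | str) -> ChannelRole:
    return key if isinstance(key, ChannelRole) else ChannelRole[str(key)]


@dataclass
class MultiChannelField:
    """One imaged field: ``pixels`` has shape (channels, height, width).

    Parameters
    ----------
    pixels
        Per-channel 2-D intensity grids stacked on axis 0; non-negative.
    pixel_size_um
        Micrometres per pixel edge (> 0).
    channel_map
        Mapping of :class:`ChannelRole` (or its name) to channel index.
    bit_depth
        Bits per sample of the native data; full scale is ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_map: Mapping[ChannelRole, int]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (C, H, W); got shape {self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.channel_map = {_as_role(k): int(v) for k, v in dict(self.channel_map).items()}
        n = self.pixels.shape[0]
        for role, idx in self.channel_map.items():
            if not 0 <= idx < n:
                raise IndexError(
                    f"channel index out of range: role {role.value} -> {idx}, file has {n} channel(s)"
                )
        if int(self.bit_depth) <= 0:
            raise ValueError("bit_depth must be positive")
        self.bit_depth = int(self.bit_depth)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    def has_role(self, role: ChannelRole | str) -> bool:
        return _as_role(role) in self.channel_map

    def channel(self, role: ChannelRole | str) -> np.ndarray:
        """Return the 2-D intensity grid bound to ``role``."""
        role = _as_role(role)
        if role not in self.channel_map:
            raise KeyError(f"no channel bound to role {role.value}")
        return self.pixels[self.channel_map[role]]

    def require_classification_roles(self) -> None:
        missing = [r.value for r in CLASSIFICATION_ROLES if r not in self.channel_map]
        if missing:
            raise ValueError(
                "vesicle classification needs GFP_LC3, RFP_LC3 and CTSD bound; "
                f"missing: {', '.join(missing)}"
            )

    def with_channel(self, role: ChannelRole | str, plane: np.ndarray) -> "MultiChannelField":
        """Return a new field with ``plane`` appended and bound to ``role``."""
        role = _as_role(role)
        if role in self.channel_map:
            raise ValueError(f"role {role.value} already bound")
        plane = np.asarray(plane)
        if plane.shape != self.shape:
            raise ValueError(f"plane shape {plane.shape} != field shape {self.shape}")
        pixels = np.concatenate([self.pixels, plane[None].astype(self.pixels.dtype, copy=False)])
        cmap = dict(self.channel_map)
        cmap[role] = self.n_channels
        return MultiChannelField(pixels, self.pixel_size_um, cmap, self.bit_depth)


@dataclass
class ROILabelMask:
    """Integer label map: 0 = background, k > 0 = neuron/ROI k."""

    labels: np.ndarray
    kind: MaskKind = MaskKind.PERIKARYON

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.issubdtype(lab.dtype, np.floating) and np.all(lab == np.round(lab)):
                lab = lab.astype(np.int32)
            else:
                raise ValueError("labels must be integers")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab
        self.kind = MaskKind(self.kind)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)


def _normalise_axes(arr: np.ndarray) -> np.ndarray:
    """Coerce a TIFF array to (C, H, W), accepting planar and interleaved dialects."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    # Channel axes are small (<= 8); spatial axes are large in confocal exports.
    if arr.shape[0] <= 8 <= arr.shape[-1]:
        return arr  # planar: page per channel
    if arr.shape[-1] <= 8 <= arr.shape[0]:
        return np.moveaxis(arr, -1, 0)  # interleaved: samples per pixel
    return arr  # ambiguous tiny image: treat axis 0 as channels


def _default_bit_depth(dtype: np.dtype) -> int:
    if np.issubdtype(dtype, np.integer):
        return int(np.iinfo(dtype).bits)
    return 16


def load_field(
    path: str | Path,
    channel_map: Mapping[ChannelRole | str, int],
    pixel_size_um: float,
    bit_depth: int | None = None,
) -> MultiChannelField:
    """Read a TIFF/OME-TIFF field and bind channel roles.

    Raises ``FileNotFoundError`` for a missing file and ``IndexError`` when a
    declared channel index does not exist in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _normalise_axes(tifffile.imread(path))
    return MultiChannelField(
        arr,
        pixel_size_um=pixel_size_um,
        channel_map=channel_map,
        bit_depth=bit_depth if bit_depth is not None else _default_bit_depth(arr.dtype),
    )


def save_field(field: MultiChannelField, path: str | Path) -> Path:
    """Write a field losslessly as a planar multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, field.pixels, photometric="minisblack", planarconfig="separate")
    return path


def load_roi_mask(
    path: str | Path,
    expected_shape: tuple[int, int] | None = None,
    kind: MaskKind | str = MaskKind.PERIKARYON,
) -> ROILabelMask:
    """Read an integer label image (TIFF or 16-bit PNG) as an ROI mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    mask = ROILabelMask(arr, kind=MaskKind(kind))
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(f"mask shape {mask.shape} != expected {tuple(expected_shape)}")
    return mask


def save_roi_mask(mask: ROILabelMask, path: str | Path) -> Path:
    path = Path(path)
    lab = mask.labels
    if path.suffix.lower() == ".png":
        if lab.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed 16-bit PNG range")
        iio.imwrite(path, lab.astype(np.uint16))
    else:
        tifffile.imwrite(path, lab)
    return path


#: Stable column schema of the per-vesicle table.
VESICLE_TABLE_COLUMNS = [
    "vesicle_id",
    "neuron_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "area_um2",
    "mean_r",
    "mean_g",
    "mean_b",
    "hue_deg",
    "saturation_pct",
    "subtype",
]


def write_vesicle_table(
    vesicles: Iterable, path: str | Path, metadata: Mapping[str, object] | None = None
) -> Path:
    """Write one CSV row per vesicle (UTF-8, '.' decimal separator).

    ``metadata`` key/value pairs (e.g. the effective subtype rules) are echoed
    as ``# key: value`` comment lines above the header.
    """
    path = Path(path)
    rows = [
        {
            "vesicle_id": v.id,
            "neuron_id": v.neuron_id,
            "centroid_row": v.centroid[0],
            "centroid_col": v.centroid[1],
            "area_px": v.area_px,
            "area_um2": v.area_um2,
            "mean_r": v.mean_r,
            "mean_g": v.mean_g,
            "mean_b": v.mean_b,
            "hue_deg": v.hue_deg,
            "saturation_pct": v.saturation_pct,
            "subtype": getattr(v.subtype, "value", v.subtype),
        }
        for v in vesicles
    ]
    frame = pd.DataFrame(rows, columns=VESICLE_TABLE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)
    return path


def read_vesicle_table(path: str | Path) -> pd.DataFrame:
    """Read a vesicle table written by :func:`write_vesicle_table`."""
    return pd.read_csv(path, comment="#")


def read_table_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta
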