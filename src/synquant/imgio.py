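"""Calibrated multi-channel image IO and maximum-intensity projection.

Images are kept as plain numpy arrays in a role-keyed container
(:class:`ImageSet`).  Geometry downstream is physical: a pixel index
``(r, c)`` maps to ``(r * pixel_size, c * pixel_size)`` in micrometres,
origin at the top-left pixel centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_ROLES = ("cell_fill", "puncta_A", "puncta_B")


class ChannelRoleError(ValueError):
    """Invalid channel-role assignment (collision or unknown role)."""


class ChannelIndexError(IndexError):
    """Channel index outside the file's channel axis."""


@dataclass
class ImageSet:
    """Multi-channel fluorescence image (2D planes or 3D z-stacks).

    Parameters
    ----------
    channels
        Map from role (``cell_fill`` / ``puncta_A`` / ``puncta_B``) to a
        2D ``(H, W)`` or 3D ``(Z, H, W)`` intensity array.  All channels
        must share shape.
    pixel_size
        Isotropic lateral calibration in micrometres per pixel.
    z_step
        Axial step in micrometres, ``None`` for single planes.
    bit_depth
        Nominal acquisition depth (8 or 16).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    z_step: float | None = None
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageSet requires at least one channel")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree in shape: {sorted(shapes)}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ChannelRoleError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_stack(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3


def read_image(
    path: str | Path,
    channel_map: dict[str, int],
    pixel_size: float,
    z_step: float | None = None,
) -> ImageSet:
    """Read a (OME-)TIFF and assign channel roles by index.

    The file's channel axis is taken from the TIFF ``axes`` metadata when
    present, otherwise the leading axis of a 3D/4D array is assumed to be
    the channel axis.  ``pixel_size`` always wins over file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    seen: dict[int, str] = {}
    for role, idx in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ChannelRoleError(f"unknown role {role!r}")
        if idx in seen:
            raise ChannelRoleError(
                f"roles {seen[idx]!r} and {role!r} both mapped to channel {idx}"
            )
        seen[idx] = role

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
    # normalise to (C, ...) with channels leading
    if "C" in axes:
        arr = np.moveaxis(arr, axes.index("C"), 0)
    elif arr.ndim == 2:
        arr = arr[None]
    n_chan = arr.shape[0]
    for role, idx in channel_map.items():
        if not 0 <= idx < n_chan:
            raise ChannelIndexError(
                f"channel index {idx} for role {role!r} out of range [0, {n_chan})"
            )
    channels = {role: np.asarray(arr[idx]) for role, idx in channel_map.items()}
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ImageSet(channels=channels, pixel_size=pixel_size, z_step=z_step, bit_depth=bit_depth)


def write_image(image_set: ImageSet, path: str | Path) -> None:
    """Write an :class:`ImageSet` as OME-TIFF with role-named channels."""
    roles = [r for r in CHANNEL_ROLES if r in image_set.channels]
    arr = np.stack([image_set.channels[r] for r in roles], axis=0)
    axes = "CZYX" if arr.ndim == 4 else "CYX"
    ps = image_set.pixel_size
    meta = {
        "axes": axes,
        "Channel": {"Name": roles},
        "PhysicalSizeX": ps,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": ps,
        "PhysicalSizeYUnit": "µm",
    }
    if image_set.z_step is not None:
        meta["PhysicalSizeZ"] = image_set.z_step
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(Path(path), arr, ome=True, metadata=meta)


def max_project(image_set: ImageSet) -> ImageSet:
    """Maximum-intensity projection over z, per channel.

    Already-2D input is returned unchanged with a warning.
    """
    if not image_set.is_stack:
        warnings.warn("max_project called on 2D input; returning it unchanged", stacklevel=2)
        return image_set
    projected = {role: np.max(a, axis=0) for role, a in image_set.channels.items()}
    return ImageSet(
        channels=projected,
        pixel_size=image_set.pixel_size,
        z_step=None,
        bit_depth=image_set.bit_depth,
        meta=dict(image_set.meta),
    )
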