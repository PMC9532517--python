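"""Threshold-mask colocalization puncta counting and density per μm of dendrite.

The per-image adaptive threshold is ``mean + k * SD`` of the whole image
(k = 2 for puncta channels, k = 1 for the cell-fill channel); the binary
masks of the two puncta channels and the cell-fill channel are conjoined
pixelwise, connected regions with an area-equivalent diameter below
10 μm are counted as synaptic puncta, and the count is divided by the
traced dendrite length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .dendrite import DendriteTrace
from .imgio import ImageSet, max_project

SD_KINDS = ("population", "sample")


@dataclass
class ThresholdSpec:
    """Mean-plus-k-sigma threshold multipliers per channel role."""

    k_puncta: float = 2.0
    k_cell_fill: float = 1.0
    sd_kind: str = "population"

    def __post_init__(self) -> None:
        if self.k_puncta < 0 or self.k_cell_fill < 0:
            raise ValueError("threshold multipliers must be >= 0")
        if self.sd_kind not in SD_KINDS:
            raise ValueError(f"sd_kind must be one of {SD_KINDS}")


@dataclass
class PunctaObject:
    label: int
    centroid_um: tuple[float, float]  # (row, col) in μm
    area_um2: float
    equivalent_diameter_um: float


@dataclass
class PunctaResult:
    """Colocalized puncta with count and density per μm of dendrite."""

    objects: list[PunctaObject]
    count: int
    dendrite_length: float
    density: float
    size_limit: float = 10.0
    params: dict = field(default_factory=dict)


def threshold_mask(channel: np.ndarray, k: float, sd_kind: str = "population") -> np.ndarray:
    """Binary mask of pixels strictly above mean + k*SD of the whole image."""
    if sd_kind not in SD_KINDS:
        raise ValueError(f"sd_kind must be one of {SD_KINDS}")
    x = np.asarray(channel, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty channel array")
    ddof = 0 if sd_kind == "population" else 1
    thr = x.mean() + k * x.std(ddof=ddof)
    return x > thr


def colocalize(*masks: np.ndarray) -> np.ndarray:
    """Pixelwise conjunction of binary masks (triple or dual colocalization)."""
    if len(masks) < 2:
        raise ValueError("colocalize requires at least two masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shape mismatch: {sorted(shapes)}")
    return np.logical_and.reduce([np.asarray(m, dtype=bool) for m in masks])


def detect_puncta(
    coloc_mask: np.ndarray,
    pixel_size: float,
    size_limit: float = 10.0,
    min_area_px: int = 1,
    connectivity: int = 2,
) -> list[PunctaObject]:
    """Label connected components and apply the size filter.

    Components are 8-connected by default.  A component is retained iff its
    area-equivalent diameter is strictly below ``size_limit`` μm and its
    pixel area is at least ``min_area_px``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labeled = measure.label(np.asarray(coloc_mask, dtype=bool), connectivity=connectivity)
    objects: list[PunctaObject] = []
    for prop in measure.regionprops(labeled):
        if prop.area < min_area_px:
            continue
        eq_diam = float(prop.equivalent_diameter_area) * pixel_size
        if eq_diam >= size_limit:
            continue
        r, c = prop.centroid
        objects.append(
            PunctaObject(
                label=int(prop.label),
                centroid_um=(float(r) * pixel_size, float(c) * pixel_size),
                area_um2=float(prop.area) * pixel_size**2,
                equivalent_diameter_um=eq_diam,
            )
        )
    return objects


def synapse_density(
    objects: list[PunctaObject],
    dendrite_length: float,
    size_limit: float = 10.0,
    params: dict | None = None,
) -> PunctaResult:
    """Package detected objects as a density: count / dendrite length (per μm)."""
    if dendrite_length <= 0:
        raise ValueError(f"dendrite_length must be positive, got {dendrite_length}")
    count = len(objects)
    return PunctaResult(
        objects=list(objects),
        count=count,
        dendrite_length=float(dendrite_length),
        density=count / dendrite_length,
        size_limit=size_limit,
        params=dict(params or {}),
    )


def quantify_image(
    image_set: ImageSet,
    trace: DendriteTrace,
    spec: ThresholdSpec | None = None,
    mode: str = "triple",
    size_limit: float = 10.0,
    min_area_px: int = 1,
) -> PunctaResult:
    """Full quantification of one image: project, threshold, colocalize, count.

    ``mode='triple'`` conjoins both puncta masks with the cell-fill mask
    (the Synapsin/PSD95 synapse assay); ``mode='dual'`` conjoins the two
    puncta masks only (two-marker assays, e.g. a candidate synaptic
    protein apposed to PSD95).  The
    dendrite trace contributes the length denominator.
    """
    if mode not in ("triple", "dual"):
        raise ValueError("mode must be 'triple' or 'dual'")
    spec = spec or ThresholdSpec()
    if image_set.is_stack:
        image_set = max_project(image_set)
    masks = {
        role: threshold_mask(
            image_set.channels[role],
            spec.k_cell_fill if role == "cell_fill" else spec.k_puncta,
            spec.sd_kind,
        )
        for role in image_set.channels
    }
    if mode == "triple":
        coloc = colocalize(masks["puncta_A"], masks["puncta_B"], masks["cell_fill"])
    else:
        coloc = colocalize(masks["puncta_A"], masks["puncta_B"])
    objects = detect_puncta(
        coloc, image_set.pixel_size, size_limit=size_limit, min_area_px=min_area_px
    )
    return synapse_density(
        objects,
        trace.total_length,
        size_limit=size_limit,
        params={
            "mode": mode,
            "k_puncta": spec.k_puncta,
            "k_cell_fill": spec.k_cell_fill,
            "sd_kind": spec.sd_kind,
            "min_area_px": min_area_px,
            "pixel_size": image_set.pixel_size,
        },
    )
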