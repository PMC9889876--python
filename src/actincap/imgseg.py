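"""Channel binarization, morphological cleanup and nucleus/cytoplasm segmentation.

The pre-processing stages of the actin-cap analysis pipeline: a grayscale
channel is binarized (fixed threshold or Otsu), cleaned with binary
morphology, and nuclei are extracted as labeled connected components with
per-object morphometry (area, perimeter, axes, circularity).  The actin
channel foreground is then partitioned into per-cell cytoplasm regions by
nearest-nucleus assignment, so that downstream fiber detection can be
restricted to a single cell's cytoplasm.

Circularity is the classic form factor ``4*pi*Area/Perimeter**2`` — 1 for a
circle, smaller for elongated shapes.  The perimeter estimator defaults to
the Crofton formula; a raw boundary-step estimator is available for
exactness comparisons but biases the circularity of digital disks low.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, dilation, disk, erosion, opening

__all__ = [
    "BinaryMask",
    "NucleusObject",
    "CellRegion",
    "DegenerateHistogramError",
    "binarize",
    "morph_clean",
    "label_nuclei",
    "segment_cytoplasm",
    "circularity_from_area_perimeter",
]

FOREGROUND = 255
#: digital circularity may slightly exceed 1; values are clipped, not rescaled
CIRCULARITY_CAP = 1.05


class DegenerateHistogramError(ValueError):
    """Otsu thresholding requested on a constant (single-level) image."""


@dataclass
class BinaryMask:
    """A {0, 255} raster plus the provenance of its thresholding."""

    data: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        vals = np.unique(self.data)
        if not np.isin(vals, (0, FOREGROUND)).all():
            raise ValueError("binary mask may contain only 0 and 255")

    @property
    def boolean(self) -> np.ndarray:
        return self.data == FOREGROUND

    @classmethod
    def from_boolean(cls, arr: np.ndarray, method: str = "bool", threshold: float = 0.0):
        return cls(arr.astype(np.uint8) * FOREGROUND, method, threshold)


@dataclass
class NucleusObject:
    """One segmented nucleus with its morphometric descriptors."""

    label: int
    area: float  # px^2
    perimeter: float  # px
    centroid: tuple[float, float]  # (x, y)
    major_axis: float  # px
    minor_axis: float  # px
    circularity: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    pixel_mask: np.ndarray  # boolean, full-frame footprint


@dataclass
class CellRegion:
    """Per-cell cytoplasm territory paired with its nucleus."""

    nucleus: NucleusObject
    mask: np.ndarray  # boolean actin-foreground pixels of this cell
    territory: np.ndarray  # boolean nearest-nucleus partition cell
    low_quality: bool = False  # no actin foreground beyond the nucleus


def binarize(
    image: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> BinaryMask:
    """Threshold a single-channel image to a {0, 255} mask.

    ``method="fixed"`` applies the rule pixel >= threshold -> 255, else 0.
    ``method="otsu"`` derives the threshold from the intensity histogram
    first, then applies the same rule; it raises
    :class:`DegenerateHistogramError` on a constant image.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {image.shape}")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold binarization needs a threshold")
        t = float(threshold)
    elif method == "otsu":
        if image.min() == image.max():
            raise DegenerateHistogramError(
                "cannot compute an Otsu threshold on a constant image"
            )
        t = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = (image >= t).astype(np.uint8) * FOREGROUND
    return BinaryMask(data=mask, method=method, threshold=t)


_MORPH_OPS = {
    "erode": erosion,
    "dilate": dilation,
    "open": opening,
    "close": closing,
}


def morph_clean(
    mask: BinaryMask | np.ndarray, ops: list[str], kernel_radius: int = 1
) -> BinaryMask:
    """Apply an ordered sequence of binary morphology ops with a disk kernel."""
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    provenance = ("chained", 0.0)
    if isinstance(mask, BinaryMask):
        provenance = (mask.method, mask.threshold)
        current = mask.boolean
    else:
        current = np.asarray(mask) > 0
    footprint = disk(kernel_radius)
    for op in ops:
        try:
            fn = _MORPH_OPS[op]
        except KeyError:
            raise ValueError(f"unknown morphological op {op!r}") from None
        current = fn(current, footprint)
    return BinaryMask.from_boolean(current, *provenance)


def circularity_from_area_perimeter(area: float, perimeter: float) -> float:
    """Form factor 4*pi*A/P^2, clipped to (0, 1.05]."""
    if area <= 0:
        raise ValueError("degenerate object: area must be > 0")
    if perimeter <= 0:
        raise ValueError("degenerate object: perimeter must be > 0")
    return min(4.0 * math.pi * area / perimeter**2, CIRCULARITY_CAP)


def label_nuclei(
    mask: BinaryMask | np.ndarray,
    min_area: float = 100.0,
    border_policy: str = "exclude",
    perimeter_estimator: str = "crofton",
) -> list[NucleusObject]:
    """Extract nuclei as 8-connected components with morphometry.

    Components smaller than ``min_area`` are dropped; objects touching the
    frame border are excluded by default (their area and perimeter would be
    truncated).  An empty mask yields an empty list.
    """
    if border_policy not in ("exclude", "include"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    boolean = mask.boolean if isinstance(mask, BinaryMask) else np.asarray(mask) > 0
    labeled = cc_label(boolean, connectivity=2)
    objects: list[NucleusObject] = []
    rows, cols = boolean.shape
    for prop in regionprops(labeled):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == rows or c1 == cols
        if touches and border_policy == "exclude":
            continue
        perim = (
            prop.perimeter_crofton
            if perimeter_estimator == "crofton"
            else prop.perimeter
        )
        cy, cx = prop.centroid
        full = np.zeros((rows, cols), dtype=bool)
        full[labeled == prop.label] = True
        objects.append(
            NucleusObject(
                label=prop.label,
                area=float(prop.area),
                perimeter=float(perim),
                centroid=(float(cx), float(cy)),
                major_axis=float(prop.axis_major_length),
                minor_axis=float(prop.axis_minor_length),
                circularity=circularity_from_area_perimeter(prop.area, perim),
                bbox=prop.bbox,
                pixel_mask=full,
            )
        )
    return objects


def segment_cytoplasm(
    actin: np.ndarray,
    nuclei: list[NucleusObject],
    *,
    method: str = "otsu",
    threshold: float | None = None,
    clean_ops: tuple[str, ...] = ("close",),
    kernel_radius: int = 1,
) -> list[CellRegion]:
    """Partition actin foreground into per-cell regions by nearest nucleus.

    The actin channel is binarized and morphologically cleaned, then every
    foreground pixel is assigned to the nucleus whose footprint is nearest
    (Euclidean distance transform), a watershed-style split of the
    foreground.  A nucleus with no actin foreground beyond its own footprint
    is returned with its footprint as the region, flagged ``low_quality``.
    """
    actin = np.asarray(actin)
    if not nuclei:
        return []
    if actin.shape != nuclei[0].pixel_mask.shape:
        raise ValueError("actin image dimensions must match the nucleus frame")
    try:
        fg = morph_clean(
            binarize(actin, method=method, threshold=threshold),
            list(clean_ops),
            kernel_radius,
        ).boolean
    except DegenerateHistogramError:
        warnings.warn("constant actin channel; no foreground", stacklevel=2)
        fg = np.zeros(actin.shape, dtype=bool)

    seeds = np.zeros(actin.shape, dtype=np.int32)
    for nuc in nuclei:
        seeds[nuc.pixel_mask] = nuc.label
    # nearest-nucleus territory for every pixel
    _, (ir, ic) = ndi.distance_transform_edt(seeds == 0, return_indices=True)
    territory_of = seeds[ir, ic]

    regions = []
    for nuc in nuclei:
        territory = territory_of == nuc.label
        cell_fg = fg & territory
        beyond_nucleus = cell_fg & ~nuc.pixel_mask
        low_quality = not beyond_nucleus.any()
        if low_quality:
            cell_fg = nuc.pixel_mask.copy()
        regions.append(
            CellRegion(
                nucleus=nuc, mask=cell_fg, territory=territory, low_quality=low_quality
            )
        )
    return regions
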