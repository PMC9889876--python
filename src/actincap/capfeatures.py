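"""Actin-cap-like feature extraction.

Per-cell measurements of the phenotype axes that distinguish actin-cap
deficient fibroblasts: nucleus circularity and major axis, straight-line
stress-fiber detection (probabilistic Hough), the population standard
deviation of per-fiber slopes (low = parallel, organized fibers), a circular
orientation-dispersion statistic on axial angles, apical-plane linescan
intensity metrics from confocal z-stacks, and a one-dimensional "actin
network complexity" summary obtained as the leading principal component of
six fiber-network descriptors.

Slopes follow image coordinates (y grows downward): slope = (y1-y2)/(x1-x2).
Near-vertical segments make the slope unbounded and are excluded from
slope statistics (but kept for angle statistics), flagged ``vertical``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import probabilistic_hough_line

from .imgseg import (
    CellRegion,
    NucleusObject,
    binarize,
    circularity_from_area_perimeter,
    label_nuclei,
    morph_clean,
    segment_cytoplasm,
)

__all__ = [
    "Fiber",
    "CellRecord",
    "detect_fibers",
    "slope_std",
    "nucleus_circularity",
    "orientation_dispersion",
    "apical_profile",
    "fiber_network_features",
    "network_complexity",
    "extract_cell_features",
    "NETWORK_FEATURES",
]

#: |x1 - x2| at or below this marks a fiber as vertical (slope undefined)
VERTICAL_DX = 1.0


@dataclass
class Fiber:
    """One detected straight actin segment."""

    x1: float
    y1: float
    x2: float
    y2: float
    mean_intensity: float = np.nan

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def vertical(self) -> bool:
        return abs(self.x1 - self.x2) <= VERTICAL_DX

    @property
    def slope(self) -> float:
        """(y1-y2)/(x1-x2); NaN for vertical segments."""
        if self.vertical:
            return np.nan
        return (self.y1 - self.y2) / (self.x1 - self.x2)

    @property
    def angle(self) -> float:
        """Axial orientation in degrees, in [0, 180). Always defined."""
        return math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1)) % 180.0

    @property
    def midpoint(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))


@dataclass
class CellRecord:
    """Per-cell feature vector: nucleus morphometry + fiber statistics."""

    cell: int
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    circularity: float  # alias: form factor
    n_fibers: int
    n_vertical_fibers: int
    slope_std: float  # NaN when < 2 non-vertical fibers
    angle_dispersion_deg: float  # NaN when < 2 fibers
    total_fiber_length: float
    mean_fiber_length: float
    fiber_density: float  # total length / region area
    n_intersections: int
    cap_fiber_fraction: float  # fraction of fibers crossing the nucleus
    apical_mean_intensity: float = np.nan  # stack inputs only
    apical_peak_intensity: float = np.nan
    actin_cap_area: float = np.nan
    low_quality: bool = False

    @property
    def form_factor(self) -> float:
        return self.circularity


def _point_segment_distance(px, py, x1, y1, x2, y2) -> float:
    vx, vy = x2 - x1, y2 - y1
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return math.hypot(px - x1, py - y1)
    t = max(0.0, min(1.0, ((px - x1) * vx + (py - y1) * vy) / L2))
    return math.hypot(px - (x1 + t * vx), py - (y1 + t * vy))


def _axial_angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _dedupe(fibers: list[Fiber], angle_tol: float, dist_tol: float) -> list[Fiber]:
    """Suppress near-collinear duplicate Hough detections (keep longest)."""
    kept: list[Fiber] = []
    for f in sorted(fibers, key=lambda f: f.length, reverse=True):
        mx, my = f.midpoint
        dup = any(
            _axial_angle_diff(f.angle, g.angle) < angle_tol
            and _point_segment_distance(mx, my, g.x1, g.y1, g.x2, g.y2) < dist_tol
            for g in kept
        )
        if not dup:
            kept.append(f)
    return kept


def detect_fibers(
    region: CellRegion,
    actin: np.ndarray,
    min_length: float = 20.0,
    max_gap: float = 3.0,
    *,
    hough_threshold: int = 10,
    dedupe_angle_tol: float = 7.5,
    dedupe_dist_tol: float = 3.0,  # 1.5x the 2-px rendered stroke width
    seed: int = 0,
) -> list[Fiber]:
    """Detect straight actin segments inside one cell's cytoplasm region.

    Runs a probabilistic Hough line detector on the region-restricted binary
    actin foreground, drops segments shorter than ``min_length``, and merges
    near-collinear duplicate detections.  Each fiber carries its endpoints,
    slope (NaN + vertical flag when near-vertical), axial angle, and the
    mean actin intensity sampled along the segment.  Empty regions yield [].
    """
    if region.low_quality or not region.mask.any():
        return []
    segs = probabilistic_hough_line(
        region.mask,
        threshold=hough_threshold,
        line_length=int(min_length),
        line_gap=int(max_gap),
        rng=np.random.default_rng(seed),
    )
    actin = np.asarray(actin, dtype=float)
    fibers = []
    for (x1, y1), (x2, y2) in segs:
        f = Fiber(float(x1), float(y1), float(x2), float(y2))
        if f.length < min_length:
            continue
        n = max(int(f.length), 2)
        xs = np.linspace(f.x1, f.x2, n).round().astype(int)
        ys = np.linspace(f.y1, f.y2, n).round().astype(int)
        inb = (ys >= 0) & (ys < actin.shape[0]) & (xs >= 0) & (xs < actin.shape[1])
        f.mean_intensity = float(actin[ys[inb], xs[inb]].mean()) if inb.any() else np.nan
        fibers.append(f)
    return _dedupe(fibers, dedupe_angle_tol, dedupe_dist_tol)


def _slopes(fibers) -> np.ndarray:
    vals = [f.slope if isinstance(f, Fiber) else float(f) for f in fibers]
    return np.asarray(vals, dtype=float)


def slope_std(fibers) -> float:
    """Population standard deviation (divisor N) of per-fiber slopes.

    Accepts a list of :class:`Fiber` or raw slope values.  Vertical fibers
    (slope undefined) are excluded; with fewer than 2 usable slopes the
    result is NaN (a missing-value marker, never 0).
    """
    slopes = _slopes(fibers)
    slopes = slopes[~np.isnan(slopes)]
    if len(slopes) < 2:
        return float("nan")
    return float(np.std(slopes))


def nucleus_circularity(obj: NucleusObject) -> float:
    """Form factor 4*pi*Area/Perimeter^2 of a segmented nucleus."""
    return circularity_from_area_perimeter(obj.area, obj.perimeter)


def orientation_dispersion(fibers) -> float:
    """Circular spread of fiber orientations, in degrees, for axial data.

    Orientations are doubled (axial identification of theta and theta+180),
    the mean resultant length R of the doubled angles is formed, and the
    angular deviation sqrt(2*(1-R)) is halved back to the axial scale.
    0 for perfectly parallel fibers; bounded above (~40.5 deg) for uniform
    orientations.  NaN with fewer than 2 fibers.
    """
    angles = np.asarray(
        [f.angle if isinstance(f, Fiber) else float(f) for f in fibers], dtype=float
    )
    if len(angles) < 2:
        return float("nan")
    doubled = np.deg2rad(2.0 * angles)
    R = float(np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean()))
    return math.degrees(math.sqrt(max(0.0, 2.0 * (1.0 - R)))) / 2.0


def _major_axis_direction(mask: np.ndarray) -> tuple[float, float]:
    """Unit (dx, dy) of the principal axis of a boolean footprint."""
    ys, xs = np.nonzero(mask)
    pts = np.stack([xs - xs.mean(), ys - ys.mean()])
    cov = pts @ pts.T / pts.shape[1]
    w, v = np.linalg.eigh(cov)
    dx, dy = v[:, np.argmax(w)]
    return float(dx), float(dy)


def apical_profile(
    stack: np.ndarray, nucleus: NucleusObject, apical_plane: int = -1
) -> tuple[float, float]:
    """Linescan intensity metrics over the nucleus in the apical plane.

    Samples the apical z-plane along the nucleus major axis, restricted to
    the nuclear footprint, and returns (mean, peak) intensity — the two
    statistics used to grade apical (cap) actin content.  Raises if the
    nucleus is clipped by the frame border.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (planes, rows, cols) stack")
    plane = stack[apical_plane].astype(float)
    rows, cols = plane.shape
    r0, c0, r1, c1 = nucleus.bbox
    if r0 == 0 or c0 == 0 or r1 == rows or c1 == cols:
        raise ValueError(f"nucleus {nucleus.label} is clipped by the frame border")
    dx, dy = _major_axis_direction(nucleus.pixel_mask)
    cx, cy = nucleus.centroid
    half = nucleus.major_axis / 2.0 + 1.0
    ts = np.linspace(-half, half, max(int(2 * half), 2))
    xs = np.clip(np.round(cx + ts * dx).astype(int), 0, cols - 1)
    ys = np.clip(np.round(cy + ts * dy).astype(int), 0, rows - 1)
    inside = nucleus.pixel_mask[ys, xs]
    if not inside.any():  # degenerate footprint; fall back to centroid pixel
        v = float(plane[int(round(cy)), int(round(cx))])
        return v, v
    vals = plane[ys[inside], xs[inside]]
    return float(vals.mean()), float(vals.max())


def _segments_intersect(f: Fiber, g: Fiber) -> bool:
    def orient(ax, ay, bx, by, cx, cy):
        return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)

    d1 = orient(f.x1, f.y1, f.x2, f.y2, g.x1, g.y1)
    d2 = orient(f.x1, f.y1, f.x2, f.y2, g.x2, g.y2)
    d3 = orient(g.x1, g.y1, g.x2, g.y2, f.x1, f.y1)
    d4 = orient(g.x1, g.y1, g.x2, g.y2, f.x2, f.y2)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


#: the six fiber-network descriptors reduced into "actin network complexity"
NETWORK_FEATURES = [
    "n_fibers",
    "total_fiber_length",
    "mean_fiber_length",
    "angle_dispersion_deg",
    "fiber_density",
    "n_intersections",
]


def fiber_network_features(fibers: list[Fiber], region_area: float) -> dict:
    """The six per-cell descriptors of the actin fiber network."""
    n = len(fibers)
    total = float(sum(f.length for f in fibers))
    inter = sum(
        _segments_intersect(fibers[i], fibers[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    return {
        "n_fibers": n,
        "total_fiber_length": total,
        "mean_fiber_length": total / n if n else np.nan,
        "angle_dispersion_deg": orientation_dispersion(fibers),
        "fiber_density": total / region_area if region_area > 0 else np.nan,
        "n_intersections": int(inter),
    }


def network_complexity(features: pd.DataFrame) -> pd.DataFrame:
    """Reduce the six fiber-network descriptors to one complexity score.

    The descriptors are z-scored across the cohort and projected onto their
    first principal component; the sign is oriented so that higher scores
    mean denser, more complex networks (positive association with fiber
    count).  Tertile labels low / medium / high are attached.  Cells with a
    missing descriptor get a NaN score.
    """
    missing = [c for c in NETWORK_FEATURES if c not in features.columns]
    if missing:
        raise ValueError(f"missing network descriptors: {missing}")
    X = features[NETWORK_FEATURES].astype(float)
    ok = X.notna().all(axis=1)
    Z = X[ok]
    mu, sd = Z.mean(), Z.std(ddof=0)
    sd = sd.replace(0.0, 1.0)  # constant descriptors carry no signal
    Z = (Z - mu) / sd
    # leading principal component via SVD of the centered matrix
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    pc1 = vt[0]
    scores = Z.to_numpy() @ pc1
    if np.corrcoef(scores, Z["n_fibers"].to_numpy())[0, 1] < 0:
        scores = -scores
    out = features.copy()
    out["network_complexity"] = np.nan
    out.loc[ok, "network_complexity"] = scores
    q1, q2 = np.nanquantile(scores, [1 / 3, 2 / 3]) if len(scores) else (np.nan, np.nan)
    labels = pd.Series(pd.NA, index=out.index, dtype="object")
    labels[ok] = np.where(scores <= q1, "low", np.where(scores <= q2, "medium", "high"))
    out["complexity_class"] = labels
    return out


def extract_cell_features(
    nucleus_img: np.ndarray,
    actin_img: np.ndarray,
    stack: np.ndarray | None = None,
    *,
    nuc_threshold: float | None = None,
    actin_threshold: float | None = None,
    min_area: float = 100.0,
    min_length: float = 20.0,
    max_gap: float = 3.0,
    clean_ops: tuple[str, ...] = ("open",),
    kernel_radius: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Full 2D per-cell feature extraction: one row per segmented nucleus.

    Segments nuclei (Otsu unless a fixed threshold is given), cleans the
    mask, partitions the actin foreground into per-cell regions, detects
    fibers and computes the :class:`CellRecord` feature vector.  When a
    z-stack is supplied, apical linescan metrics and the actin-cap area
    (apical foreground overlapping the nuclear footprint) are added.
    """
    method = "otsu" if nuc_threshold is None else "fixed"
    mask = morph_clean(
        binarize(nucleus_img, method=method, threshold=nuc_threshold),
        list(clean_ops),
        kernel_radius,
    )
    nuclei = label_nuclei(mask, min_area=min_area)
    regions = segment_cytoplasm(
        actin_img,
        nuclei,
        method="otsu" if actin_threshold is None else "fixed",
        threshold=actin_threshold,
    )
    apical_fg = None
    if stack is not None:
        stack = np.asarray(stack)
        try:
            apical_fg = binarize(stack[-1], method="otsu").boolean
        except Exception:
            apical_fg = np.zeros(stack[-1].shape, dtype=bool)

    records = []
    for region in regions:
        nuc = region.nucleus
        fibers = detect_fibers(
            region, actin_img, min_length=min_length, max_gap=max_gap, seed=seed
        )
        net = fiber_network_features(fibers, region_area=float(region.mask.sum()))
        n_vertical = sum(f.vertical for f in fibers)
        crossing = sum(
            1
            for f in fibers
            if _fiber_crosses_footprint(f, nuc.pixel_mask)
        )
        rec = CellRecord(
            cell=nuc.label,
            area=nuc.area,
            perimeter=nuc.perimeter,
            major_axis=nuc.major_axis,
            minor_axis=nuc.minor_axis,
            circularity=nuc.circularity,
            n_fibers=net["n_fibers"],
            n_vertical_fibers=n_vertical,
            slope_std=slope_std(fibers),
            angle_dispersion_deg=net["angle_dispersion_deg"],
            total_fiber_length=net["total_fiber_length"],
            mean_fiber_length=net["mean_fiber_length"],
            fiber_density=net["fiber_density"],
            n_intersections=net["n_intersections"],
            cap_fiber_fraction=crossing / len(fibers) if fibers else np.nan,
            low_quality=region.low_quality,
        )
        if stack is not None:
            try:
                rec.apical_mean_intensity, rec.apical_peak_intensity = apical_profile(
                    stack, nuc
                )
            except ValueError:
                pass  # border-clipped nucleus: apical metrics stay NaN
            rec.actin_cap_area = float((apical_fg & nuc.pixel_mask).sum())
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])


def _fiber_crosses_footprint(f: Fiber, footprint: np.ndarray) -> bool:
    n = max(int(f.length), 2)
    xs = np.linspace(f.x1, f.x2, n).round().astype(int)
    ys = np.linspace(f.y1, f.y2, n).round().astype(int)
    inb = (
        (ys >= 0) & (ys < footprint.shape[0]) & (xs >= 0) & (xs < footprint.shape[1])
    )
    return bool(footprint[ys[inb], xs[inb]].any())
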