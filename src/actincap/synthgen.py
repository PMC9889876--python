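"""Synthetic two-channel fibroblast fields, z-stacks and motility tracks.

This module renders ground-truthed test images that emulate the phenotype
axes of adherent fibroblast cultures imaged in a nucleus channel (DNA stain)
and an F-actin channel (phalloidin): elliptical nuclei with controllable
circularity, straight stress fibers with controllable count / length /
orientation dispersion, Gaussian background noise, and persistent-random-walk
migration tracks.  Every renderer returns exact per-cell ground truth so the
measurement modules can be validated by parameter recovery.

Raster convention: row-major, origin top-left, x = column, y = row (y grows
downward, so slope signs follow image coordinates).  Images are 8-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import tifffile
from scipy.special import ellipe
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa

__all__ = [
    "SynthCellSpec",
    "SynthFieldSpec",
    "GroundTruth",
    "PlacementError",
    "render_field",
    "render_stack",
    "simulate_tracks",
    "make_field_spec",
    "write_field_tiff",
]

#: fibers closer than this to vertical are excluded from slope ground truth
NEAR_VERTICAL_DEG = 2.0


class PlacementError(RuntimeError):
    """Raised when disjoint nucleus placement fails after bounded retries."""


@dataclass
class SynthCellSpec:
    """Parameters for one rendered cell (nucleus ellipse + fiber bundle)."""

    nucleus_center: tuple[float, float]  # (x, y) px
    nucleus_semi_axes: tuple[float, float] = (20.0, 20.0)  # (a, b), a >= b
    nucleus_angle: float = 0.0  # degrees, major-axis orientation
    nucleus_intensity: int = 200
    n_fibers: int = 10
    fiber_angle_mean: float = 0.0  # degrees
    fiber_angle_sd: float = 5.0  # degrees; orientation dispersion
    fiber_length_range: tuple[float, float] = (40.0, 80.0)  # px
    fiber_intensity: int = 180
    apical_fiber_fraction: float = 0.5  # fraction drawn in the apical plane

    def __post_init__(self) -> None:
        a, b = self.nucleus_semi_axes
        if not (a >= b > 0):
            raise ValueError(f"nucleus semi-axes must satisfy a >= b > 0, got {a}, {b}")
        if not 0.0 <= self.apical_fiber_fraction <= 1.0:
            raise ValueError("apical_fiber_fraction must lie in [0, 1]")
        if self.fiber_angle_sd < 0:
            raise ValueError("fiber_angle_sd must be >= 0")

    @property
    def true_circularity(self) -> float:
        """4*pi*A/P^2 of the continuous ellipse (exact perimeter)."""
        a, b = self.nucleus_semi_axes
        area = math.pi * a * b
        perim = ellipse_perimeter(a, b)
        return 4.0 * math.pi * area / perim**2


@dataclass
class SynthFieldSpec:
    """One synthetic field: image geometry, cells, noise and seed."""

    image_size: tuple[int, int] = (512, 512)  # (rows, cols)
    cell_specs: list[SynthCellSpec] = dc_field(default_factory=list)
    noise_mean: float = 8.0
    noise_sd: float = 5.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cell_specs)


@dataclass
class GroundTruth:
    """Exact per-cell truth for a rendered field or stack."""

    cells: pd.DataFrame  # one row per cell
    fibers: pd.DataFrame  # one row per fiber segment

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact perimeter of an ellipse via the complete elliptic integral."""
    if a < b:
        a, b = b, a
    ecc2 = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(ecc2))


def _draw_thick_line_aa(img: np.ndarray, p0, p1, intensity: float) -> None:
    # anti-aliased segment of ~2 px width: base stroke plus a 1-px
    # perpendicular offset stroke
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    if norm == 0:
        return
    # unit normal
    nx, ny = -dy / norm, dx / norm
    for off in (0.0, 1.0):
        rr, cc, val = line_aa(
            int(round(y0 + ny * off)),
            int(round(x0 + nx * off)),
            int(round(y1 + ny * off)),
            int(round(x1 + nx * off)),
        )
        keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        rr, cc, val = rr[keep], cc[keep], val[keep]
        np.maximum.at(img, (rr, cc), val * intensity)


def _sample_fibers(cell: SynthCellSpec, rng: np.random.Generator) -> list[dict]:
    """Draw fiber endpoints for one cell; returns per-fiber truth records."""
    cx, cy = cell.nucleus_center
    a, b = cell.nucleus_semi_axes
    lo, hi = cell.fiber_length_range
    n_apical = int(round(cell.apical_fiber_fraction * cell.n_fibers))
    fibers = []
    for i in range(cell.n_fibers):
        angle = rng.normal(cell.fiber_angle_mean, cell.fiber_angle_sd)
        length = rng.uniform(lo, hi)
        # fiber midpoints scattered over the cell body around the nucleus
        mx = cx + rng.uniform(-1.5 * a, 1.5 * a)
        my = cy + rng.uniform(-1.5 * a, 1.5 * a)
        th = math.radians(angle)
        hx, hy = 0.5 * length * math.cos(th), 0.5 * length * math.sin(th)
        axial = angle % 180.0
        near_vertical = abs(axial - 90.0) < NEAR_VERTICAL_DEG
        fibers.append(
            {
                "x1": mx - hx,
                "y1": my - hy,
                "x2": mx + hx,
                "y2": my + hy,
                "angle_deg": axial,
                "slope": math.tan(th) if not near_vertical else np.nan,
                "near_vertical": near_vertical,
                "length_px": length,
                "apical": i < n_apical,
            }
        )
    return fibers


def _render(
    spec: SynthFieldSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render nucleus, basal-actin and apical-actin float rasters + truth."""
    rows, cols = spec.image_size
    rng = np.random.default_rng(spec.seed)
    nuc = np.zeros((rows, cols), dtype=np.float64)
    actin_basal = np.zeros_like(nuc)
    actin_apical = np.zeros_like(nuc)

    cell_records, fiber_records = [], []
    for label, cell in enumerate(spec.cell_specs, start=1):
        cx, cy = cell.nucleus_center
        a, b = cell.nucleus_semi_axes
        rr, cc = draw_ellipse(
            cy, cx, b, a, shape=(rows, cols), rotation=math.radians(cell.nucleus_angle)
        )
        nuc[rr, cc] = cell.nucleus_intensity
        fibers = _sample_fibers(cell, rng)
        for f in fibers:
            target = actin_apical if f["apical"] else actin_basal
            _draw_thick_line_aa(
                target, (f["x1"], f["y1"]), (f["x2"], f["y2"]), cell.fiber_intensity
            )
            fiber_records.append({"cell": label, **f})
        slopes = [f["slope"] for f in fibers if not f["near_vertical"]]
        cell_records.append(
            {
                "cell": label,
                "center_x": cx,
                "center_y": cy,
                "true_circularity": cell.true_circularity,
                "true_major_axis": 2.0 * a,
                "true_minor_axis": 2.0 * b,
                "n_fibers": cell.n_fibers,
                "n_apical_fibers": sum(f["apical"] for f in fibers),
                "true_slope_sd": float(np.std(slopes)) if len(slopes) >= 2 else np.nan,
                "true_angle_sd_deg": cell.fiber_angle_sd,
            }
        )

    truth = GroundTruth(
        cells=pd.DataFrame(
            cell_records,
            columns=[
                "cell",
                "center_x",
                "center_y",
                "true_circularity",
                "true_major_axis",
                "true_minor_axis",
                "n_fibers",
                "n_apical_fibers",
                "true_slope_sd",
                "true_angle_sd_deg",
            ],
        ),
        fibers=pd.DataFrame(
            fiber_records,
            columns=[
                "cell",
                "x1",
                "y1",
                "x2",
                "y2",
                "angle_deg",
                "slope",
                "near_vertical",
                "length_px",
                "apical",
            ],
        ),
    )
    return nuc, actin_basal, actin_apical, truth


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_field(spec: SynthFieldSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a 2D field: (nucleus channel, actin channel, ground truth).

    The actin channel is the projection of all fibers (basal + apical).
    Identical spec and seed give bit-identical images.
    """
    nuc, basal, apical, truth = _render(spec)
    rows, cols = spec.image_size
    rng = np.random.default_rng([spec.seed, 1])
    noise = lambda: rng.normal(spec.noise_mean, spec.noise_sd, size=(rows, cols))
    # projected actin channel: max projection of basal and apical fibers
    return _to_uint8(nuc + noise()), _to_uint8(np.maximum(basal, apical) + noise()), truth


def render_stack(
    spec: SynthFieldSpec, n_planes: int = 3
) -> tuple[np.ndarray, GroundTruth]:
    """Render a confocal-style z-stack of ``n_planes`` >= 3 actin planes.

    Plane 0 is basal (substrate-attached fibers), the middle plane carries
    the nucleus signal, and the last plane is apical (cap fibers above the
    nucleus, assigned per ``apical_fiber_fraction``).  Intermediate planes
    beyond the three canonical ones contain background noise only.
    """
    if n_planes < 3:
        raise ValueError(f"a z-stack needs at least 3 planes, got {n_planes}")
    nuc, basal, apical, truth = _render(spec)
    rows, cols = spec.image_size
    rng = np.random.default_rng([spec.seed, 2])
    stack = np.empty((n_planes, rows, cols), dtype=np.uint8)
    mid = n_planes // 2
    for z in range(n_planes):
        if z == 0:
            plane = basal
        elif z == mid:
            plane = nuc
        elif z == n_planes - 1:
            plane = apical
        else:
            plane = 0.0
        stack[z] = _to_uint8(
            plane + rng.normal(spec.noise_mean, spec.noise_sd, size=(rows, cols))
        )
    return stack, truth


def make_field_spec(
    n_cells: int,
    image_size: tuple[int, int] = (512, 512),
    *,
    semi_axes: tuple[float, float] = (20.0, 20.0),
    n_fibers: int = 10,
    fiber_angle_sd: float = 5.0,
    apical_fiber_fraction: float = 0.5,
    noise_sd: float = 5.0,
    nucleus_intensity: int = 200,
    fiber_intensity: int = 180,
    seed: int = 0,
    disjoint: bool = True,
    margin: float = 12.0,
    max_tries: int = 2000,
) -> SynthFieldSpec:
    """Place ``n_cells`` nuclei (disjoint by default) and build a field spec.

    Nucleus centers are sampled uniformly inside the frame with a border
    margin; with ``disjoint=True`` candidate centers closer than the sum of
    major semi-axes plus ``margin`` to an accepted one are rejected, with a
    bounded number of retries (:class:`PlacementError` on failure).
    Per-cell fiber orientation means are drawn uniformly over [0, 180).
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_size
    a = max(semi_axes)
    pad = a + margin
    if rows <= 2 * pad or cols <= 2 * pad:
        raise PlacementError("image too small to contain any nucleus with margin")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_cells} disjoint nuclei in {image_size} "
                f"after {max_tries} tries"
            )
        tries += 1
        cand = (rng.uniform(pad, cols - pad), rng.uniform(pad, rows - pad))
        if disjoint and any(
            math.hypot(cand[0] - x, cand[1] - y) < 2 * a + margin for x, y in centers
        ):
            continue
        centers.append(cand)
    specs = [
        SynthCellSpec(
            nucleus_center=c,
            nucleus_semi_axes=semi_axes,
            nucleus_angle=float(rng.uniform(0, 180)),
            nucleus_intensity=nucleus_intensity,
            n_fibers=n_fibers,
            fiber_angle_mean=float(rng.uniform(0, 180)),
            fiber_angle_sd=fiber_angle_sd,
            fiber_intensity=fiber_intensity,
            apical_fiber_fraction=apical_fiber_fraction,
        )
        for c in centers
    ]
    return SynthFieldSpec(
        image_size=image_size, cell_specs=specs, noise_sd=noise_sd, seed=seed
    )


# ---------------------------------------------------------------------------
# motility ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimTrack:
    """Ground-truth migration track: positions at fixed frame intervals."""

    cell_id: int
    positions: np.ndarray  # (n_steps + 1, 2) of (x, y)
    frame_interval_min: float = 10.0

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.frame_interval_min


def simulate_tracks(
    n_cells: int,
    n_steps: int,
    speed: float,
    persistence: float,
    seed: int = 0,
    *,
    frame_interval_min: float = 10.0,
    arena: float = 1000.0,
) -> list[SimTrack]:
    """Persistent random walks with exact step length ``speed`` px/frame.

    ``persistence`` in [0, 1] controls directional memory: the per-step
    turning angle is uniform on ``[-pi*(1-p), pi*(1-p)]``, so ``p=1`` gives
    ballistic straight-line motion and ``p=0`` an uncorrelated random walk.
    Starting positions are scattered uniformly in ``[0, arena]^2``.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    half_width = math.pi * (1.0 - persistence)
    tracks = []
    for cid in range(n_cells):
        pos = np.empty((n_steps + 1, 2))
        pos[0] = rng.uniform(0, arena, size=2)
        heading = rng.uniform(0, 2 * math.pi)
        for k in range(n_steps):
            if half_width > 0:
                heading += rng.uniform(-half_width, half_width)
            pos[k + 1, 0] = pos[k, 0] + speed * math.cos(heading)
            pos[k + 1, 1] = pos[k, 1] + speed * math.sin(heading)
        tracks.append(
            SimTrack(cell_id=cid, positions=pos, frame_interval_min=frame_interval_min)
        )
    return tracks


def write_field_tiff(
    path,
    nucleus: np.ndarray,
    actin: np.ndarray,
    truth: GroundTruth | None = None,
    truth_path=None,
) -> None:
    """Write a two-page TIFF (nucleus page, actin page) + optional truth CSV."""
    tifffile.imwrite(path, np.stack([nucleus, actin]))
    if truth is not None and truth_path is not None:
        truth.cells.to_csv(truth_path, index=False)
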