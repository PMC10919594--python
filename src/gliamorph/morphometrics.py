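"""The 16 single-cell shape descriptors.

Given one isolated binary cell mask the module measures, in this canonical
order:

======  ======================================================  =========
name    meaning                                                 units
======  ======================================================  =========
NOB     number of skeleton branches                             count
FD      box-counting fractal dimension of the cell contour      --
LAC     gliding-box lacunarity, mean (sigma/mu)^2 over scales   --
CA      cell area (foreground pixel count)                      um^2
CHA     convex hull area                                        um^2
DEN     density, CA / CHA                                       --
CP      cell perimeter (outline pixel count)                    um
CHSR    convex hull span ratio, major / minor hull axis         --
MSACH   maximum span across the convex hull                     um
CHP     convex hull perimeter (polygon edge length)             um
R       roughness, CP / CHP                                     --
CC      cell circularity, 4*pi*CA / CP^2                        --
CHC     convex hull circularity, 4*pi*CHA / CHP^2               --
TRMM    max/min hull radius ratio (centroid to hull vertices)   --
MR      mean hull radius                                        um
DOB     diameter of the minimum circle enclosing the hull       um
======  ======================================================  =========

Note the deliberately mixed perimeter conventions inherited from common
practice in microglial morphometry: CP counts boundary *pixels* while CHP
is a true polygon edge length. As a consequence R can fall slightly below
1 for very compact digital shapes, and CC of a digital disk exceeds the
continuous value 1; neither is an error. Geometry is computed in pixels
and converted to micrometres at the very end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (
    BinaryCellMask,
    cell_geometry,
    outline_pixels,
    skeletonize_mask,
)

__all__ = [
    "DESCRIPTOR_NAMES",
    "BoxCountCurve",
    "LacunarityCurve",
    "MorphometricVector",
    "circularity",
    "count_branches",
    "fractal_dimension_boxcount",
    "lacunarity_gliding",
    "measure_cell",
]

#: canonical descriptor order used by every feature table in the package
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "NOB", "FD", "LAC", "CA", "CHA", "DEN", "CP", "CHSR",
    "MSACH", "CHP", "R", "CC", "CHC", "TRMM", "MR", "DOB",
)


@dataclass(frozen=True)
class MorphometricVector:
    NOB: float
    FD: float
    LAC: float
    CA: float
    CHA: float
    DEN: float
    CP: float
    CHSR: float
    MSACH: float
    CHP: float
    R: float
    CC: float
    CHC: float
    TRMM: float
    MR: float
    DOB: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in DESCRIPTOR_NAMES}


@dataclass(frozen=True)
class BoxCountCurve:
    """log-log box-count data behind a fractal-dimension estimate."""

    box_sizes_px: np.ndarray  # decreasing
    counts: np.ndarray  # mean occupied boxes per size (over grid offsets)
    slope: float


@dataclass(frozen=True)
class LacunarityCurve:
    box_sizes_px: np.ndarray
    lambda_values: np.ndarray  # (n_sizes, n_offsets) of (sigma/mu)^2
    aggregate: float


# ---------------------------------------------------------------------------
# Skeleton branches
# ---------------------------------------------------------------------------

_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def count_branches(skeleton: np.ndarray) -> int:
    """Branch count of a 1-px-wide skeleton.

    Pixels are classified by their 8-neighbor count: endpoints (1 neighbor),
    slab pixels (2) and junction pixels (>= 3). Adjacent junction pixels
    merge into one junction node. A branch is a maximal run of slab pixels
    joining two nodes (or closing a cycle), plus any direct node-node
    adjacency. Isolated pixels contribute 0; a simple open curve counts 1.
    """
    skel = np.asarray(skeleton, dtype=bool)
    coords = [tuple(p) for p in np.argwhere(skel)]
    if not coords:
        return 0
    pix = set(coords)
    nbrs = {
        p: [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS8 if (p[0] + dr, p[1] + dc) in pix]
        for p in pix
    }
    degree = {p: len(n) for p, n in nbrs.items()}
    junction_px = {p for p, d in degree.items() if d >= 3}

    # merge 8-adjacent junction pixels into junction nodes
    node_of: dict[tuple[int, int], int] = {}
    next_node = 0
    for p in sorted(junction_px):
        if p in node_of:
            continue
        stack = [p]
        node_of[p] = next_node
        while stack:
            q = stack.pop()
            for r in nbrs[q]:
                if r in junction_px and r not in node_of:
                    node_of[r] = next_node
                    stack.append(r)
        next_node += 1
    for p, d in degree.items():
        if d == 1:  # each endpoint is its own node
            node_of[p] = next_node
            next_node += 1

    slab = {p for p, d in degree.items() if d == 2 and p not in node_of}

    branches = 0
    # slab runs: each connected component of slab pixels is one branch
    seen: set[tuple[int, int]] = set()
    for p in sorted(slab):
        if p in seen:
            continue
        stack = [p]
        seen.add(p)
        while stack:
            q = stack.pop()
            for r in nbrs[q]:
                if r in slab and r not in seen:
                    seen.add(r)
                    stack.append(r)
        branches += 1
    # direct node-node adjacencies with no slab between (e.g. a 2-px line)
    direct = set()
    for p in node_of:
        for r in nbrs[p]:
            if r in node_of and node_of[r] != node_of[p]:
                direct.add(frozenset((node_of[p], node_of[r])))
    branches += len(direct)
    return branches


# ---------------------------------------------------------------------------
# Fractal dimension and lacunarity
# ---------------------------------------------------------------------------

def _dyadic_sizes(extent: int, min_size: int = 2) -> np.ndarray:
    """Dyadic box sizes from min_size up to extent // 4, decreasing."""
    top = extent // 4
    sizes = []
    s = min_size
    while s <= top:
        sizes.append(s)
        s *= 2
    return np.array(sizes[::-1], dtype=int)


class InsufficientScaleError(ValueError):
    """Pattern too small to support >= 2 box sizes."""


def fractal_dimension_boxcount(
    points: np.ndarray,
    grid_offsets: int = 4,
    sizes: np.ndarray | None = None,
) -> tuple[float, BoxCountCurve]:
    """Box-counting fractal dimension of a pixel point set.

    For each box size and each of ``grid_offsets`` diagonal grid shifts the
    number of boxes containing at least one point is counted; counts are
    averaged over offsets and FD is the least-squares slope of
    log N versus log(1/eps). Smooth curves give FD near 1; space-filling
    contours approach 2.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=int))
    if pts.size == 0:
        raise ValueError("empty point set")
    mins = pts.min(axis=0)
    pts = pts - mins
    extent = int(pts.max() + 1)
    if sizes is None:
        sizes = _dyadic_sizes(extent)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size < 2:
        raise InsufficientScaleError(
            f"pattern extent {extent} px supports {sizes.size} box sizes; >= 2 required"
        )
    counts = np.empty(sizes.size, dtype=float)
    for i, s in enumerate(sizes):
        per_offset = []
        for k in range(grid_offsets):
            shift = (k * s) // grid_offsets
            boxes = (pts + shift) // s
            per_offset.append(np.unique(boxes, axis=0).shape[0])
        counts[i] = float(np.mean(per_offset))
    slope = float(np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)[0])
    return slope, BoxCountCurve(box_sizes_px=sizes, counts=counts, slope=slope)


def lacunarity_gliding(
    pattern: np.ndarray,
    sizes: np.ndarray | None = None,
    grid_offsets: int = 4,
) -> tuple[float, LacunarityCurve]:
    """Gliding-box lacunarity of a binary pattern.

    The supplied raster's full extent is tiled with boxes of each size
    (every box overlapping the region is included; the per-box density is
    the foreground count divided by the box INTERSECTION with the region,
    so a completely filled raster scores exactly 0). For each size and grid
    offset lambda = (sigma/mu)^2 over box densities (population sigma);
    LAC is the mean over sizes and offsets. High values flag gappy,
    heterogeneous silhouettes. Crop the raster to the cell's bounding box
    beforehand to analyze a cell independent of its canvas.
    """
    region = np.asarray(pattern, dtype=bool).astype(float)
    if not region.any():
        raise ValueError("empty pattern")
    h, w = region.shape
    if sizes is None:
        sizes = _dyadic_sizes(min(h, w))
        if sizes.size == 0:
            sizes = np.array([max(1, min(h, w) // 2)], dtype=int)
    sizes = np.asarray(sizes, dtype=int)

    # summed-area table: box sum = S[rj,cj] - S[ri,cj] - S[rj,ci] + S[ri,ci]
    sat = np.zeros((h + 1, w + 1))
    sat[1:, 1:] = region.cumsum(0).cumsum(1)

    lam = np.empty((sizes.size, grid_offsets), dtype=float)
    for i, s in enumerate(sizes):
        for k in range(grid_offsets):
            shift = (k * s) // grid_offsets
            # box starts covering [0, h) x [0, w) with the grid shifted
            r_lo = np.arange(-shift, h, s).clip(0, h)
            r_hi = (np.arange(-shift, h, s) + s).clip(0, h)
            c_lo = np.arange(-shift, w, s).clip(0, w)
            c_hi = (np.arange(-shift, w, s) + s).clip(0, w)
            keep_r = r_hi > r_lo
            keep_c = c_hi > c_lo
            r_lo, r_hi = r_lo[keep_r], r_hi[keep_r]
            c_lo, c_hi = c_lo[keep_c], c_hi[keep_c]
            sums = (
                sat[np.ix_(r_hi, c_hi)]
                - sat[np.ix_(r_lo, c_hi)]
                - sat[np.ix_(r_hi, c_lo)]
                + sat[np.ix_(r_lo, c_lo)]
            )
            areas = np.outer(r_hi - r_lo, c_hi - c_lo)
            d = (sums / areas).ravel()
            mu = d.mean()
            lam[i, k] = 0.0 if mu == 0 else float(d.var() / mu**2)
    aggregate = float(lam.mean())
    return aggregate, LacunarityCurve(box_sizes_px=sizes, lambda_values=lam, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Scalar descriptors and assembly
# ---------------------------------------------------------------------------

def circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter^2; equals 1 for a mathematical circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def measure_cell(mask: BinaryCellMask) -> MorphometricVector:
    """All 16 descriptors of one isolated cell, in physical units."""
    ps = mask.pixel_size_um
    geom = cell_geometry(mask)

    ca = mask.area_px * ps**2
    cha = geom.hull_area_px2 * ps**2
    chp = geom.hull_perimeter_px * ps
    cp = geom.outline.shape[0] * ps
    den = ca / cha
    chsr = geom.major_axis_px / geom.minor_axis_px
    msach = geom.major_axis_px * ps
    r = cp / chp
    cc = circularity(ca, cp)
    chc = circularity(cha, chp)

    centroid = np.asarray(geom.hull_centroid)
    radii = np.hypot(*(geom.hull - centroid).T)
    trmm = float(radii.max() / radii.min())
    mr = float(radii.mean()) * ps
    dob = 2.0 * geom.bounding_circle[1] * ps

    nob = count_branches(geom.skeleton)
    fd, _ = fractal_dimension_boxcount(geom.outline)
    fg = np.argwhere(mask.raster)
    (r0, c0), (r1, c1) = fg.min(axis=0), fg.max(axis=0) + 1
    lac, _ = lacunarity_gliding(mask.raster[r0:r1, c0:c1])

    return MorphometricVector(
        NOB=float(nob), FD=fd, LAC=lac, CA=ca, CHA=cha, DEN=den, CP=cp,
        CHSR=chsr, MSACH=msach, CHP=chp, R=r, CC=cc, CHC=chc,
        TRMM=trmm, MR=mr, DOB=dob,
    )
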