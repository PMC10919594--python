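"""Synthetic microglia: binary silhouettes and group-parameterized feature tables.

Real Iba-1 micrographs are not distributable with the package, so this
module provides two substitutes that make every downstream stage testable:

* :func:`generate_cell_mask` draws binary microglia-like silhouettes (a
  filled soma disk plus recursively branching, jittered processes) for four
  morphotype presets spanning the ramified-to-ameboid activation continuum.
  The presets map onto the four sampled regions of a rat glioma model:
  ramified (contralateral control, CL), hyper-ramified (peritumoral brain
  zone, PBZ), reactive (tumor interface, INT) and ameboid (tumor core, TUM).
* :func:`generate_feature_table` samples per-cell descriptor vectors from
  the published per-region means and standard deviations (80 cells per
  region), drawing each of the 16 descriptors independently from a normal
  distribution and clipping to the descriptor's valid range.

The tables deliberately ignore inter-descriptor correlation: only marginal
moments are published, so synthetic cohorts are *easier* to separate along
single axes but lack the covariance structure of real cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, line
from skimage.morphology import disk as disk_footprint

from .geometry import BinaryCellMask
from .morphometrics import DESCRIPTOR_NAMES

__all__ = [
    "GROUP_SPECS_TABLE1",
    "PBZ_CLUSTER_SPECS",
    "PRESETS",
    "ROI_ORDER",
    "GroupSpec",
    "MorphotypePreset",
    "generate_cell_mask",
    "generate_feature_table",
    "render_micrograph",
]

#: fixed region order used for tie-breaks and display throughout
ROI_ORDER: tuple[str, ...] = ("CL", "PBZ", "INT", "TUM")

DEFAULT_PIXEL_SIZE_UM = 0.081
DEFAULT_CANVAS = (1024, 1024)  # ~83 um field at 0.081 um/px


@dataclass(frozen=True)
class MorphotypePreset:
    """Generator settings for one microglial morphotype."""

    name: str
    roi: str
    soma_radius_um: float
    n_primary_branches: int
    branch_length_um: float
    branch_width_um: float
    branching_prob: float
    tortuosity: float  # angular jitter SD per step, radians
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if min(self.soma_radius_um, self.branch_width_um, self.pixel_size_um) <= 0:
            raise ValueError("lengths must be positive")
        if self.branch_length_um < 0 or self.n_primary_branches < 0:
            raise ValueError("branch length and count must be nonnegative")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must be in [0, 1]")


PRESETS: dict[str, MorphotypePreset] = {
    # surveillant cell: small soma, long thin highly branched processes
    "ramified": MorphotypePreset(
        name="ramified", roi="CL", soma_radius_um=2.8, n_primary_branches=7,
        branch_length_um=27.0, branch_width_um=0.55, branching_prob=0.40,
        tortuosity=0.60,
    ),
    "hyper_ramified": MorphotypePreset(
        name="hyper_ramified", roi="PBZ", soma_radius_um=3.0, n_primary_branches=6,
        branch_length_um=20.0, branch_width_um=0.65, branching_prob=0.42,
        tortuosity=0.70,
    ),
    "reactive": MorphotypePreset(
        name="reactive", roi="INT", soma_radius_um=3.6, n_primary_branches=4,
        branch_length_um=9.0, branch_width_um=0.85, branching_prob=0.15,
        tortuosity=0.60,
    ),
    # phagocytic cell: large soma, at most a couple of stubby processes
    "ameboid": MorphotypePreset(
        name="ameboid", roi="TUM", soma_radius_um=5.2, n_primary_branches=2,
        branch_length_um=3.5, branch_width_um=1.3, branching_prob=0.05,
        tortuosity=0.40,
    ),
}


@dataclass(frozen=True)
class GroupSpec:
    """Marginal normal model for one region's 16-descriptor distribution."""

    roi_label: str
    mean: np.ndarray
    sd: np.ndarray
    n_cells: int = 80

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (len(DESCRIPTOR_NAMES),) or sd.shape != mean.shape:
            raise ValueError(
                f"mean and sd must be length-{len(DESCRIPTOR_NAMES)} vectors in the "
                f"canonical order {DESCRIPTOR_NAMES}"
            )
        if (sd < 0).any():
            raise ValueError("sd must be nonnegative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


def _spec(roi: str, stats: dict[str, tuple[float, float]], n: int = 80) -> GroupSpec:
    return GroupSpec(
        roi_label=roi,
        mean=np.array([stats[k][0] for k in DESCRIPTOR_NAMES]),
        sd=np.array([stats[k][1] for k in DESCRIPTOR_NAMES]),
        n_cells=n,
    )


# Published per-region descriptor means and SDs (80 cells per region).
# Units: CA/CHA um^2; CP/MSACH/CHP/MR/DOB um; the rest dimensionless.
GROUP_SPECS_TABLE1: dict[str, GroupSpec] = {
    "CL": _spec("CL", {
        "NOB": (246.46, 144.04), "FD": (1.48, 0.06), "LAC": (1.10, 0.24),
        "CA": (214.44, 55.86), "CHA": (2097.07, 764.75), "DEN": (0.11, 0.03),
        "CP": (1477.42, 420.66), "CHSR": (1.41, 0.25), "MSACH": (65.39, 12.48),
        "CHP": (174.78, 31.06), "R": (8.48, 1.95), "CC": (0.0013, 0.0005),
        "CHC": (0.84, 0.05), "TRMM": (1.58, 0.26), "MR": (29.03, 5.24),
        "DOB": (65.88, 12.33),
    }),
    "PBZ": _spec("PBZ", {
        "NOB": (137.14, 69.06), "FD": (1.42, 0.06), "LAC": (1.23, 0.27),
        "CA": (137.86, 50.19), "CHA": (1099.68, 472.48), "DEN": (0.14, 0.04),
        "CP": (798.17, 312.40), "CHSR": (1.58, 0.34), "MSACH": (49.13, 10.90),
        "CHP": (127.76, 27.65), "R": (6.08, 1.55), "CC": (0.0037, 0.003),
        "CHC": (0.80, 0.06), "TRMM": (1.74, 0.36), "MR": (21.44, 4.58),
        "DOB": (49.43, 10.83),
    }),
    "INT": _spec("INT", {
        "NOB": (46.95, 33.12), "FD": (1.38, 0.07), "LAC": (0.96, 0.22),
        "CA": (71.53, 42.01), "CHA": (269.33, 180.32), "DEN": (0.29, 0.09),
        "CP": (257.11, 147.69), "CHSR": (2.04, 0.7), "MSACH": (26.02, 6.56),
        "CHP": (65.07, 17.97), "R": (3.74, 1.21), "CC": (0.02, 0.01),
        "CHC": (0.72, 0.10), "TRMM": (2.05, 0.63), "MR": (11.24, 2.98),
        "DOB": (26.20, 6.62),
    }),
    "TUM": _spec("TUM", {
        "NOB": (10.99, 7.23), "FD": (1.22, 0.06), "LAC": (0.61, 0.22),
        "CA": (60.06, 41.94), "CHA": (110.93, 70.15), "DEN": (0.56, 0.18),
        "CP": (77.70, 34.12), "CHSR": (2.25, 0.83), "MSACH": (17.82, 5.97),
        "CHP": (43.11, 13.74), "R": (1.76, 0.36), "CC": (0.15, 0.09),
        "CHC": (0.69, 0.12), "TRMM": (2.39, 0.87), "MR": (7.72, 2.56),
        "DOB": (17.90, 5.98),
    }),
}

# Published descriptor statistics of the two morphotype clusters found within
# the independent 200-cell peritumoral sample (n = 69 and n = 131).
PBZ_CLUSTER_SPECS: dict[str, GroupSpec] = {
    "PBZ1": _spec("PBZ1", {
        "NOB": (90.29, 38.17), "FD": (1.41, 0.07), "LAC": (1.08, 0.24),
        "CA": (90.29, 29.58), "CHA": (572.45, 217.38), "DEN": (0.17, 0.06),
        "CP": (482.17, 156.26), "CHSR": (1.67, 0.44), "MSACH": (36.42, 6.98),
        "CHP": (93.63, 17.91), "R": (5.10, 1.31), "CC": (6.61e-3, 6.5e-3),
        "CHC": (0.79, 0.09), "TRMM": (1.79, 0.46), "MR": (15.85, 2.94),
        "DOB": (36.68, 7.05),
    }, n=69),
    "PBZ2": _spec("PBZ2", {
        "NOB": (151.85, 48.47), "FD": (1.44, 0.05), "LAC": (1.27, 0.30),
        "CA": (163.45, 44.74), "CHA": (1336.24, 378.51), "DEN": (0.13, 0.03),
        "CP": (945.39, 243.22), "CHSR": (1.41, 0.25), "MSACH": (52.49, 7.88),
        "CHP": (140.24, 19.09), "R": (6.70, 1.24), "CC": (2.54e-3, 1.1e-3),
        "CHC": (0.84, 0.05), "TRMM": (1.59, 0.24), "MR": (23.45, 3.34),
        "DOB": (52.99, 7.79),
    }, n=131),
}


# ---------------------------------------------------------------------------
# Binary silhouette generator
# ---------------------------------------------------------------------------

class CanvasTooSmallError(ValueError):
    pass


def _required_extent_px(preset: MorphotypePreset) -> int:
    ps = preset.pixel_size_um
    # branches wander, so their radial reach is bounded by the path length
    reach = (preset.soma_radius_um + preset.branch_length_um + preset.branch_width_um) / ps
    return int(np.ceil(2 * reach)) + 8  # margin keeps foreground off the border


def _draw_branch(
    rng: np.random.Generator,
    start: np.ndarray,
    angle: float,
    length_px: float,
    preset: MorphotypePreset,
    segments: list[tuple[int, int, int, int]],
    depth: int,
    step_px: float = 4.0,
) -> None:
    """One jittered stroke with stochastic side branches (recursive).

    ``tortuosity`` is the SD of the cumulative angular drift over the whole
    branch; side branches arrive as a Poisson process along the path with
    rate ``branching_prob`` per ~3 um, each taking a fraction of the
    remaining length. Recursion depth is capped at 3.
    """
    pos = start.astype(float)
    remaining = length_px
    if remaining < 1.0:
        return
    per_step_sigma = preset.tortuosity * np.sqrt(step_px / length_px)
    spawn_per_px = preset.branching_prob * preset.pixel_size_um / 3.0
    while remaining > 0.5:
        step = min(step_px, remaining)
        angle += rng.normal(0.0, per_step_sigma)
        new = pos + step * np.array([np.sin(angle), np.cos(angle)])
        segments.append((int(round(pos[0])), int(round(pos[1])),
                         int(round(new[0])), int(round(new[1]))))
        pos = new
        remaining -= step
        if depth < 3 and remaining > 8.0 and rng.random() < spawn_per_px * step:
            child_len = remaining * rng.uniform(0.5, 0.9)
            side = rng.choice([-1.0, 1.0]) * rng.normal(0.7, 0.15)
            _draw_branch(rng, pos.copy(), angle + side, child_len, preset,
                         segments, depth + 1, step_px)


def generate_cell_mask(
    preset: MorphotypePreset | str,
    seed: int,
    canvas_px: tuple[int, int] = DEFAULT_CANVAS,
) -> BinaryCellMask:
    """Draw one binary microglia-like silhouette.

    The soma is a filled disk at the canvas center; each primary process is
    a recursive jittered stroke rooted on the soma rim, so the result is a
    single 8-connected component. Deterministic for a fixed (preset, seed).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    ps = preset.pixel_size_um
    need = _required_extent_px(preset)
    if min(canvas_px) < need:
        raise CanvasTooSmallError(
            f"canvas {canvas_px} too small: preset '{preset.name}' needs at "
            f"least {need} px per side (soma + maximal branch extent)"
        )
    rng = np.random.default_rng(seed)
    h, w = canvas_px
    center = np.array([h / 2.0, w / 2.0])
    soma_r = preset.soma_radius_um / ps

    canvas = np.zeros(canvas_px, dtype=bool)
    rr, cc = disk(tuple(center), soma_r, shape=canvas_px)
    canvas[rr, cc] = True

    segments: list[tuple[int, int, int, int]] = []
    n = preset.n_primary_branches
    for b in range(n):
        angle = 2 * np.pi * b / n + rng.normal(0.0, 0.25)
        root = center + (soma_r - 1.0) * np.array([np.sin(angle), np.cos(angle)])
        length = max(2.0, rng.normal(1.0, 0.25) * preset.branch_length_um) / ps
        _draw_branch(rng, root, angle, length, preset, segments, depth=0)

    if segments:
        strokes = np.zeros(canvas_px, dtype=bool)
        for r0, c0, r1, c1 in segments:
            rr, cc = line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            strokes[rr[keep], cc[keep]] = True
        half_width = max(1, int(round(preset.branch_width_um / ps / 2.0)))
        strokes = ndimage.binary_dilation(strokes, structure=disk_footprint(half_width))
        canvas |= strokes

    # branches root inside the soma, but keep only the component through it
    labels, nlab = ndimage.label(canvas, structure=np.ones((3, 3), dtype=bool))
    canvas = labels == labels[int(center[0]), int(center[1])]
    canvas[0, :] = canvas[-1, :] = False
    canvas[:, 0] = canvas[:, -1] = False
    return BinaryCellMask(canvas, pixel_size_um=ps)


def render_micrograph(
    mask: BinaryCellMask,
    noise_sd: float = 0.0,
    background_texture_scale: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a mask as a DAB-like grayscale crop: dark cell, light background.

    ``background_texture_scale`` is the correlation length (in pixels) of a
    smooth multiplicative background texture; 0 gives a flat background.
    Additive pixel noise has SD ``noise_sd`` on the 0-255 intensity scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.where(mask.raster, 60.0, 200.0)
    if background_texture_scale > 0:
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, mask.raster.shape), background_texture_scale
        )
        tex_sd = texture.std()
        if tex_sd > 0:
            img += np.where(mask.raster, 0.0, 25.0 * texture / tex_sd)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Feature tables from printed group statistics
# ---------------------------------------------------------------------------

_EPS = 1e-6

# (lower, upper) validity bounds per descriptor after the normal draw
_CLIP_BOUNDS: dict[str, tuple[float, float]] = {
    "NOB": (_EPS, np.inf), "FD": (_EPS, np.inf), "LAC": (_EPS, np.inf),
    "CA": (_EPS, np.inf), "CHA": (_EPS, np.inf), "DEN": (_EPS, 1.0),
    "CP": (_EPS, np.inf), "CHSR": (1.0, np.inf), "MSACH": (_EPS, np.inf),
    "CHP": (_EPS, np.inf), "R": (_EPS, np.inf), "CC": (_EPS, 1.0),
    "CHC": (_EPS, 1.0), "TRMM": (1.0, np.inf), "MR": (_EPS, np.inf),
    "DOB": (_EPS, np.inf),
}


def generate_feature_table(
    specs: list[GroupSpec] | dict[str, GroupSpec],
    seed: int,
) -> pd.DataFrame:
    """Sample a cells x descriptors table from per-group marginal normals.

    Each descriptor is drawn independently from N(mean, sd) for its group
    and clipped to its valid range (areas and lengths positive, density and
    circularities in (0, 1], axis-ratio descriptors >= 1). Returns a
    DataFrame with columns ``cell_id``, ``roi`` and the 16 descriptors in
    canonical order; deterministic for a fixed seed.
    """
    if isinstance(specs, dict):
        specs = list(specs.values())
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        draws = rng.normal(
            spec.mean[None, :], spec.sd[None, :], size=(spec.n_cells, len(DESCRIPTOR_NAMES))
        )
        lo = np.array([_CLIP_BOUNDS[n][0] for n in DESCRIPTOR_NAMES])
        hi = np.array([_CLIP_BOUNDS[n][1] for n in DESCRIPTOR_NAMES])
        draws = np.clip(draws, lo[None, :], hi[None, :])
        df = pd.DataFrame(draws, columns=list(DESCRIPTOR_NAMES))
        df.insert(0, "roi", spec.roi_label)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", [f"cell_{i:04d}" for i in range(len(table))])
    return table
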