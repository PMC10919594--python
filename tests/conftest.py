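import numpy as np
import pandas as pd
import pytest

from gliamorph import synthetic


@pytest.fixture(scope="session")
def table1_table() -> pd.DataFrame:
    """One synthetic 4 x 80-cell cohort drawn from the published group stats."""
    return synthetic.generate_feature_table(synthetic.GROUP_SPECS_TABLE1, seed=0)


@pytest.fixture(scope="session")
def small_cells() -> dict:
    """A few measured silhouettes per preset on a compact canvas (cached)."""
    from gliamorph.morphometrics import measure_cell

    out = {}
    for name in ("reactive", "ameboid"):
        cells = []
        for seed in range(3):
            mask = synthetic.generate_cell_mask(name, seed=seed, canvas_px=(420, 420))
            cells.append((mask, measure_cell(mask)))
        out[name] = cells
    return out


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n^3) hull-vertex identification: a point is a vertex iff some edge
    through it has all other points strictly on one side."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if (cross >= -1e-9).all() or (cross <= 1e-9).all():
                verts.add(tuple(pts[i]))
                verts.add(tuple(pts[j]))
    return verts


def brute_force_min_circle(points: np.ndarray) -> float:
    """Minimum enclosing radius by exhausting all pair- and triple-circles."""
    from itertools import combinations

    pts = np.asarray(points, dtype=float)

    def covers(c, r):
        return (np.hypot(*(pts - c).T) <= r + 1e-9).all()

    best = np.inf
    for a, b in combinations(pts, 2):
        c = (a + b) / 2
        r = np.hypot(*(a - c))
        if covers(c, r):
            best = min(best, r)
    for a, b, c in combinations(pts, 3):
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        r = np.hypot(*(a - center))
        if covers(center, r):
            best = min(best, r)
    return float(best)
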