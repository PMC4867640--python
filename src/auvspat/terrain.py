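"""Terrain analysis: depth contours, distances to them, and KS tests.

The hill's influence on fish placement is assessed by extracting depth
contours from the bathymetry (marching squares), computing the shortest
distance from every image to each contour via a rasterised Euclidean
distance transform, and comparing the distance distributions of
fish-bearing vs fish-free images with a bootstrapped two-sample
Kolmogorov-Smirnov test whose null is built by pooled resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage import measure

from .synthetic import BathymetryGrid

__all__ = [
    "ContourSet",
    "KsResult",
    "extract_contours",
    "distance_to_contour",
    "ks_statistic",
    "bootstrap_ks",
]

DEFAULT_LEVELS = (4800.0, 4750.0, 4700.0, 4650.0)


@dataclass
class ContourSet:
    """Isoline polylines per depth level, in world metres."""

    levels: list[float]
    lines: dict[float, list[np.ndarray]]  # level -> list of (k, 2) e/n arrays
    cell_size: float
    warnings: list[str] = field(default_factory=list)

    def vertices(self, level: float) -> np.ndarray:
        segs = self.lines.get(level, [])
        if not segs:
            return np.empty((0, 2))
        return np.concatenate(segs, axis=0)


def extract_contours(
    bathy: BathymetryGrid, levels=DEFAULT_LEVELS
) -> ContourSet:
    """Marching-squares isolines of the depth grid at the given levels.

    Levels outside the grid's depth range are omitted, with a warning
    record on the returned set.
    """
    lines: dict[float, list[np.ndarray]] = {}
    kept: list[float] = []
    warnings: list[str] = []
    dmin, dmax = float(bathy.depth.min()), float(bathy.depth.max())
    for level in levels:
        level = float(level)
        if not (dmin <= level <= dmax):
            warnings.append(
                f"level {level} outside depth range [{dmin:.1f}, {dmax:.1f}]; omitted"
            )
            continue
        raw = measure.find_contours(bathy.depth, level)
        polys = []
        for rc in raw:
            e = bathy.origin_easting + rc[:, 1] * bathy.cell_size
            n = bathy.origin_northing + rc[:, 0] * bathy.cell_size
            polys.append(np.column_stack([e, n]))
        if polys:
            lines[level] = polys
            kept.append(level)
        else:
            warnings.append(f"level {level} produced no isoline; omitted")
    return ContourSet(levels=kept, lines=lines, cell_size=bathy.cell_size, warnings=warnings)


def distance_to_contour(
    points: np.ndarray,
    contours: ContourSet,
    cell_size: float | None = None,
) -> dict[float, np.ndarray]:
    """Shortest distance (m) from each point to each contour level.

    Each contour is rasterised onto a grid at ``cell_size`` resolution
    (default: the contour's source cell size) and a Euclidean distance
    transform is sampled at the query points; the result agrees with
    exact point-to-segment distance to within cell_size * sqrt(2).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if cell_size is None:
        cell_size = contours.cell_size
    out: dict[float, np.ndarray] = {}
    for level in contours.levels:
        verts = [_densify(seg, cell_size / 2.0) for seg in contours.lines[level]]
        allv = np.concatenate(verts, axis=0)
        e_min = min(allv[:, 0].min(), points[:, 0].min()) - 2 * cell_size
        e_max = max(allv[:, 0].max(), points[:, 0].max()) + 2 * cell_size
        n_min = min(allv[:, 1].min(), points[:, 1].min()) - 2 * cell_size
        n_max = max(allv[:, 1].max(), points[:, 1].max()) + 2 * cell_size
        nc = int(np.ceil((e_max - e_min) / cell_size)) + 1
        nr = int(np.ceil((n_max - n_min) / cell_size)) + 1
        mask = np.ones((nr, nc), dtype=bool)
        j = np.clip(np.rint((allv[:, 0] - e_min) / cell_size).astype(int), 0, nc - 1)
        i = np.clip(np.rint((allv[:, 1] - n_min) / cell_size).astype(int), 0, nr - 1)
        mask[i, j] = False  # contour cells are the zero set
        edt = distance_transform_edt(mask, sampling=cell_size)
        pj = np.clip(np.rint((points[:, 0] - e_min) / cell_size).astype(int), 0, nc - 1)
        pi = np.clip(np.rint((points[:, 1] - n_min) / cell_size).astype(int), 0, nr - 1)
        out[level] = edt[pi, pj]
    return out


def _densify(seg: np.ndarray, step: float) -> np.ndarray:
    """Insert vertices so consecutive polyline points are <= step apart."""
    if seg.shape[0] < 2:
        return seg
    d = np.hypot(*np.diff(seg, axis=0).T)
    n_sub = np.maximum(1, np.ceil(d / step).astype(int))
    pieces = []
    for k in range(seg.shape[0] - 1):
        frac = np.linspace(0.0, 1.0, n_sub[k], endpoint=False)
        pieces.append(seg[k] + frac[:, None] * (seg[k + 1] - seg[k]))
    pieces.append(seg[-1:])
    return np.concatenate(pieces, axis=0)


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D (sup-norm ECDF distance)."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic requires two non-empty samples")
    values = np.concatenate([a, b])[None, :]
    return float(_ks_d_rows(values, a.size)[0])


def _ks_d_rows(values: np.ndarray, n_a: int) -> np.ndarray:
    """Row-wise KS D for pooled-value matrices.

    ``values`` has shape (r, n_a + n_b): the first ``n_a`` columns of each
    row are sample A, the rest sample B.  Tie-aware: the ECDF difference
    is evaluated only at the last element of each run of equal values.
    """
    r, n = values.shape
    n_b = n - n_a
    w = np.empty(n)
    w[:n_a] = 1.0 / n_a
    w[n_a:] = -1.0 / n_b
    order = np.argsort(values, axis=1, kind="stable")
    sv = np.take_along_axis(values, order, axis=1)
    sw = np.take_along_axis(np.broadcast_to(w, (r, n)), order, axis=1)
    cdf_diff = np.cumsum(sw, axis=1)
    run_end = np.ones((r, n), dtype=bool)
    run_end[:, :-1] = sv[:, 1:] != sv[:, :-1]
    # D is in [0, 1] exactly; cumsum rounding can stray by ~1 ulp
    return np.clip(np.max(np.abs(np.where(run_end, cdf_diff, 0.0)), axis=1), 0.0, 1.0)


@dataclass(frozen=True)
class KsResult:
    d: float
    p: float
    n_a: int
    n_b: int
    n_boot: int


def bootstrap_ks(
    sample_a,
    sample_b,
    n_boot: int = 1000,
    seed: int = 0,
) -> KsResult:
    """Bootstrapped two-sample KS test.

    The null distribution of D is built by drawing both groups (sizes
    preserved) with replacement from the pooled sample, which is
    consistent with the no-difference hypothesis and robust to ties.
    p = (1 + #{D_boot >= D_obs}) / (n_boot + 1), so p is never zero.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    d_obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = pooled.size
    rng = np.random.default_rng(seed)
    d_boot = np.empty(n_boot)
    chunk = max(1, int(4e6 // max(n, 1)))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        res = pooled[rng.integers(0, n, size=(k, n))]
        d_boot[done : done + k] = _ks_d_rows(res, a.size)
        done += k
    p = (1.0 + np.count_nonzero(d_boot >= d_obs - 1e-12)) / (n_boot + 1.0)
    return KsResult(d=d_obs, p=float(p), n_a=a.size, n_b=b.size, n_boot=n_boot)
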