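"""Dispersion analyses: 1D neighbour-K along transects and quadrat VMR.

Broad-scale surveys are analysed as a single concatenated transect: the
neighbour-K statistic K(t) is the mean number of other individuals
within along-track distance t of a typical individual, compared against
a Monte-Carlo null in which the same number of individuals is scattered
uniformly over the survey's images.  For presentation K is normalised to
L(t) = K(t) / mean(K_null(t)) - 1, so a random pattern sits at 0 and the
Monte-Carlo envelope brackets it.

Fine-scale grids are analysed as 11 x 11 quadrats: the variance-to-mean
ratio (VMR) of per-cell fish counts is compared against a Monte-Carlo
null that reassigns each photograph (carrying its fish count) to a
uniformly random cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FootprintSet

__all__ = [
    "TransectSequence",
    "KNull",
    "DispersionResult",
    "QuadratResult",
    "neighbour_k",
    "neighbour_k_positions",
    "mc_envelope",
    "normalize_L",
    "dispersion_analysis",
    "quadrat_centres",
    "quadrat_assign",
    "vmr",
    "mc_vmr",
]


@dataclass
class TransectSequence:
    """Ordered retained images with along-track positions and counts.

    Survey lines are assumed contiguous: positions are image rank times
    ``metres_per_image`` (the median within-line image spacing), so turn
    gaps between lines vanish, as in an image-count parameterisation.
    """

    positions: np.ndarray  # metres along the concatenated track, increasing
    counts: pd.DataFrame  # one column per taxon plus "all", one row per image
    metres_per_image: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return int(self.positions.size)

    @classmethod
    def from_observations(
        cls,
        footprints: FootprintSet,
        obs: pd.DataFrame,
        taxa: list[str] | None = None,
        metres_per_image: float | None = None,
    ) -> "TransectSequence":
        order = np.argsort(footprints.timestamp, kind="mergesort")
        fps = footprints.subset(order)
        if metres_per_image is None:
            d = np.hypot(*np.diff(fps.centre, axis=0).T)
            metres_per_image = float(np.median(d)) if d.size else 1.0
        n = len(fps)
        pos = np.arange(n) * metres_per_image
        idx = pd.Series(np.arange(n), index=fps.image_id)
        if taxa is None:
            taxa = sorted(obs["taxon"].unique().tolist()) if len(obs) else []
        counts = pd.DataFrame(0.0, index=np.arange(n), columns=list(taxa) + ["all"])
        if len(obs):
            rows = idx.loc[obs["image_id"]].to_numpy()
            for taxon, r in zip(obs["taxon"].to_numpy(), rows):
                if taxon in counts.columns:
                    counts.iloc[r, counts.columns.get_loc(taxon)] += 1
                counts.iloc[r, counts.columns.get_loc("all")] += 1
        return cls(positions=pos, counts=counts, metres_per_image=metres_per_image)

    def individual_positions(self, taxon: str = "all") -> np.ndarray:
        """Along-track position of each individual (repeats for multi-fish images)."""
        c = self.counts[taxon].to_numpy().astype(int)
        return np.repeat(self.positions, c)

    def default_t_grid(self, images_per_interval: int = 100, n_t: int = 20) -> np.ndarray:
        step = images_per_interval * self.metres_per_image
        return step * np.arange(1, n_t + 1)


def neighbour_k_positions(positions: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """K(t) = mean number of other individuals within t, from 1D positions."""
    x = np.sort(np.asarray(positions, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("neighbour K undefined for fewer than 2 individuals")
    t = np.asarray(t_grid, dtype=float)
    hi = np.searchsorted(x, x[None, :].T + t[None, :], side="right")
    lo = np.searchsorted(x, x[None, :].T - t[None, :], side="left")
    return ((hi - lo - 1).sum(axis=0)) / n


def neighbour_k(
    seq: TransectSequence, taxon: str = "all", t_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Observed K(t) for one taxon; returns (t_grid, K)."""
    if t_grid is None:
        t_grid = seq.default_t_grid()
    k = neighbour_k_positions(seq.individual_positions(taxon), t_grid)
    return np.asarray(t_grid, dtype=float), k


@dataclass
class KNull:
    """Monte-Carlo null distribution of K(t) under random image placement."""

    t_grid: np.ndarray
    k_sims: np.ndarray  # (n_sim, n_t)
    n: int

    @property
    def mean(self) -> np.ndarray:
        return self.k_sims.mean(axis=0)

    def envelope(self, level: float = 95.0) -> tuple[np.ndarray, np.ndarray]:
        half = (100.0 - level) / 2.0
        lo = np.percentile(self.k_sims, half, axis=0)
        hi = np.percentile(self.k_sims, 100.0 - half, axis=0)
        return lo, hi


def mc_envelope(
    seq: TransectSequence,
    n: int,
    t_grid: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> KNull:
    """Null K(t) by placing n individuals on n distinct random images.

    Each replicate selects n images uniformly without replacement (one
    individual per selected image) and recomputes K; this is the
    random-relabelling null for a pattern of n individuals observed over
    the survey's image sequence.
    """
    if n > len(seq):
        raise ValueError("cannot place more individuals than images")
    if t_grid is None:
        t_grid = seq.default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    m = len(seq)
    sims = np.empty((n_sim, t_grid.size))
    for s in range(n_sim):
        pos = seq.positions[rng.choice(m, size=n, replace=False)]
        sims[s] = neighbour_k_positions(pos, t_grid)
    return KNull(t_grid=t_grid, k_sims=sims, n=n)


def normalize_L(k_obs: np.ndarray, k_null_mean: np.ndarray) -> np.ndarray:
    """L(t) = K(t) / mean(K_null(t)) - 1; NaN where the null mean is zero.

    Anchors a random pattern at L = 0; the ratio form is used (rather
    than a difference) because K scales with intensity.
    """
    k_obs = np.asarray(k_obs, dtype=float)
    k_null_mean = np.asarray(k_null_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k_null_mean > 0, k_obs / k_null_mean - 1.0, np.nan)
    return out


@dataclass
class DispersionResult:
    """L(t) curve with Monte-Carlo envelope and per-t verdicts."""

    taxon: str
    t_grid: np.ndarray
    k_obs: np.ndarray
    l_obs: np.ndarray
    l_env_low: np.ndarray
    l_env_high: np.ndarray
    verdict: np.ndarray  # "clustered" | "random" | "dispersed" | "undefined"
    n: int
    n_sim: int

    def any_clustered(self) -> bool:
        return bool(np.any(self.verdict == "clustered"))

    def any_dispersed(self) -> bool:
        return bool(np.any(self.verdict == "dispersed"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_m": self.t_grid,
                "K": self.k_obs,
                "L": self.l_obs,
                "env_low": self.l_env_low,
                "env_high": self.l_env_high,
                "verdict": self.verdict,
            }
        )


def dispersion_analysis(
    seq: TransectSequence,
    taxon: str = "all",
    t_grid: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> DispersionResult:
    """Full neighbour-K dispersion test for one taxon."""
    if t_grid is None:
        t_grid = seq.default_t_grid()
    t_grid, k_obs = neighbour_k(seq, taxon, t_grid)
    n = int(seq.counts[taxon].sum())
    null = mc_envelope(seq, n, t_grid, n_sim=n_sim, seed=seed)
    k_lo, k_hi = null.envelope()
    mean = null.mean
    l_obs = normalize_L(k_obs, mean)
    verdict = np.where(
        ~np.isfinite(l_obs),
        "undefined",
        np.where(k_obs > k_hi, "clustered", np.where(k_obs < k_lo, "dispersed", "random")),
    ).astype(object)
    return DispersionResult(
        taxon=taxon,
        t_grid=t_grid,
        k_obs=k_obs,
        l_obs=l_obs,
        l_env_low=normalize_L(k_lo, mean),
        l_env_high=normalize_L(k_hi, mean),
        verdict=verdict,
        n=n,
        n_sim=n_sim,
    )


def quadrat_centres(
    origin: tuple[float, float], extent: tuple[float, float], n: int = 11
) -> np.ndarray:
    """The n x n grid-cell centres spanning a fine survey extent.

    Centres sit at the nominal intersections of the horizontal and
    vertical survey lines: a uniform n x n lattice over the extent.
    Returned as (n*n, 2) in row-major (northing-major) order.
    """
    ex = origin[0] + np.linspace(0.0, extent[0], n)
    ny = origin[1] + np.linspace(0.0, extent[1], n)
    ee, nn = np.meshgrid(ex, ny)
    return np.column_stack([ee.ravel(), nn.ravel()])


def quadrat_assign(
    points: np.ndarray,
    origin: tuple[float, float],
    extent: tuple[float, float],
    n: int = 11,
) -> np.ndarray:
    """Assign each point to the nearest of the n x n cell centres.

    Ties break toward the lower cell index.  Points beyond the extent
    plus half a cell spacing raise an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dx = extent[0] / (n - 1)
    dy = extent[1] / (n - 1)
    fx = (pts[:, 0] - origin[0]) / dx
    fy = (pts[:, 1] - origin[1]) / dy
    if np.any(fx < -0.5) or np.any(fx > n - 0.5) or np.any(fy < -0.5) or np.any(fy > n - 0.5):
        raise ValueError("point outside quadrat extent plus half-spacing margin")
    # Round half toward lower index: ceil(f - 0.5) assigns the midpoint down.
    col = np.clip(np.ceil(fx - 0.5).astype(int), 0, n - 1)
    row = np.clip(np.ceil(fy - 0.5).astype(int), 0, n - 1)
    return row * n + col


def vmr(cell_counts: np.ndarray) -> float:
    """Variance-to-mean ratio of quadrat counts (sample variance, n-1)."""
    c = np.asarray(cell_counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("VMR undefined for all-zero quadrat counts")
    return float(c.var(ddof=1) / c.mean())


@dataclass
class QuadratResult:
    """Observed quadrat VMR with its Monte-Carlo null interval."""

    taxon: str
    cell_counts: np.ndarray  # length n_cells
    vmr_obs: float
    ci_low: float
    ci_high: float
    verdict: str  # clustered | random | dispersed
    n_fish: int
    n_mc: int


def mc_vmr(
    image_cells: np.ndarray,
    image_counts: np.ndarray,
    n_cells: int = 121,
    n_mc: int = 10_000,
    seed: int = 0,
    taxon: str = "all",
) -> QuadratResult:
    """Monte-Carlo dispersion test of the quadrat variance-to-mean ratio.

    ``image_cells``/``image_counts`` give each photograph's observed cell
    and fish count.  Each replicate reassigns every photograph (its count
    travelling with it) to a uniformly random cell and recomputes the
    VMR; the observed value is judged against the 2.5-97.5 percentile
    interval.
    """
    cells = np.asarray(image_cells, dtype=int)
    counts = np.asarray(image_counts, dtype=float)
    if counts.sum() < 1:
        raise ValueError("quadrat test requires at least one fish")
    obs_cells = np.bincount(cells, weights=counts, minlength=n_cells)
    vmr_obs = vmr(obs_cells)

    # Zero-count photographs never alter cell counts; only fish-bearing
    # images are reassigned explicitly.
    nz = counts > 0
    nz_counts = counts[nz]
    k = nz_counts.size
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, n_cells, size=(n_mc, k))
    flat = (np.arange(n_mc)[:, None] * n_cells + draw).ravel()
    sims = np.bincount(
        flat, weights=np.broadcast_to(nz_counts, (n_mc, k)).ravel(), minlength=n_mc * n_cells
    ).reshape(n_mc, n_cells)
    total = nz_counts.sum()
    mean = total / n_cells
    var = (np.sum(sims**2, axis=1) - n_cells * mean**2) / (n_cells - 1)
    vmr_sims = var / mean
    lo, hi = np.percentile(vmr_sims, [2.5, 97.5])
    # float-ulp guard so degenerate nulls (identical replicates) read random
    tol = 1e-9 * max(1.0, abs(vmr_obs))
    if vmr_obs > hi + tol:
        verdict = "clustered"
    elif vmr_obs < lo - tol:
        verdict = "dispersed"
    else:
        verdict = "random"
    return QuadratResult(
        taxon=taxon,
        cell_counts=obs_cells,
        vmr_obs=vmr_obs,
        ci_low=float(lo),
        ci_high=float(hi),
        verdict=verdict,
        n_fish=int(round(float(counts.sum()))),
        n_mc=n_mc,
    )
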