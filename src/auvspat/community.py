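"""Assemblage comparisons: Bray-Curtis, ANOSIM and SIMPER.

Because individual images are too sparse to be community samples, each
camera's retained images are randomly subdivided into a few equal-size
groups; per-group per-taxon densities form the abundance matrix.  Group
structure is tested with one-way ANOSIM (rank-based, one-sided toward
clustering) on Bray-Curtis dissimilarities, and significant contrasts
are decomposed with SIMPER into per-taxon contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .geometry import FootprintSet

__all__ = [
    "AnosimResult",
    "partition_samples",
    "abundance_matrix",
    "presence_absence",
    "bray_curtis",
    "dissimilarity_matrix",
    "anosim",
    "anosim_r",
    "simper",
]


def partition_samples(
    footprints: FootprintSet, k: int = 4, seed: int = 0
) -> list[np.ndarray]:
    """Split a camera's images into k equal-size random subsets.

    Returns k index arrays into ``footprints``; the remainder after
    dividing by k is dropped.  Reproducible under a fixed seed.
    """
    n = len(footprints)
    if n < k:
        raise ValueError(f"need at least {k} images, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    size = n // k
    return [np.sort(perm[i * size : (i + 1) * size]) for i in range(k)]


def abundance_matrix(
    groups: dict[str, tuple[FootprintSet, pd.DataFrame]],
    k: int = 4,
    seed: int = 0,
    taxa: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subset per-taxon density matrix across labelled cameras.

    ``groups`` maps a group label (e.g. camera) to its retained
    footprints and observation table.  Each group contributes k samples;
    entries are densities in individuals km^-2.  Returns (matrix,
    labels).
    """
    if taxa is None:
        taxa = sorted(
            {t for _, obs in groups.values() for t in obs["taxon"].unique()}
        )
    rows = []
    labels = []
    names = []
    for gi, (label, (fps, obs)) in enumerate(sorted(groups.items())):
        parts = partition_samples(fps, k=k, seed=seed + gi)
        id_of = pd.Series(np.arange(len(fps)), index=fps.image_id)
        img_row = id_of.loc[obs["image_id"]].to_numpy() if len(obs) else np.empty(0, int)
        for si, part in enumerate(parts):
            area = float(fps.area[part].sum()) / 1e6
            in_part = np.isin(img_row, part)
            sub = obs.iloc[np.flatnonzero(in_part)] if len(obs) else obs
            row = [
                (len(sub[sub["taxon"] == t]) / area if area > 0 else 0.0) for t in taxa
            ]
            rows.append(row)
            labels.append(label)
            names.append(f"{label}_{si}")
    mat = pd.DataFrame(rows, index=names, columns=taxa, dtype=float)
    return mat, pd.Series(labels, index=names, name="group")


def presence_absence(matrix: pd.DataFrame) -> pd.DataFrame:
    """0/1 transform of an abundance matrix (idempotent)."""
    return (matrix > 0).astype(float)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity: sum|u-v| / sum(u+v), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def dissimilarity_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Square Bray-Curtis dissimilarity matrix between samples (rows)."""
    return squareform(pdist(matrix.to_numpy(dtype=float), metric="braycurtis"))


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_perm: int


def anosim_r(dm: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R statistic from a square dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise dissimilarities, ranked with average ranks for
    ties.
    """
    labels = np.asarray(labels)
    n = labels.size
    iu = np.triu_indices(n, k=1)
    d = np.asarray(dm)[iu]
    ranks = rankdata(d)
    within = labels[iu[0]] == labels[iu[1]]
    if within.all() or not within.any():
        raise ValueError("ANOSIM needs both within- and between-group pairs")
    m = d.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """One-way ANOSIM permutation test on Bray-Curtis dissimilarities.

    One-sided toward positive R (group clustering), the conventional
    alternative; p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >=2 groups with >=2 samples each")
    dm = dissimilarity_matrix(matrix)
    r_obs = anosim_r(dm, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_perm = anosim_r(dm, rng.permutation(labels))
        if r_perm >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(r=r_obs, p=(1 + hits) / (n_perm + 1), n_perm=n_perm)


def simper(matrix: pd.DataFrame, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """SIMPER decomposition of mean between-group Bray-Curtis dissimilarity.

    For every between-group sample pair the per-taxon terms
    |u_i - v_i| / sum(u + v) are averaged; they sum to the overall mean
    between-group dissimilarity.  Returns a table ranked by contribution
    with percentage and cumulative percentage columns.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("SIMPER implemented for exactly 2 groups")
    a = matrix.to_numpy(dtype=float)[labels == groups[0]]
    b = matrix.to_numpy(dtype=float)[labels == groups[1]]
    contribs = np.zeros(matrix.shape[1])
    n_pairs = 0
    for u in a:
        for v in b:
            denom = (u + v).sum()
            if denom == 0:
                raise ValueError("Bray-Curtis undefined for two all-zero samples")
            contribs += np.abs(u - v) / denom
            n_pairs += 1
    contribs /= n_pairs
    total = contribs.sum()
    out = pd.DataFrame(
        {
            "taxon": matrix.columns,
            "mean_" + str(groups[0]): a.mean(axis=0),
            "mean_" + str(groups[1]): b.mean(axis=0),
            "contribution": contribs,
            "pct": 100.0 * contribs / total if total > 0 else 0.0,
        }
    ).sort_values("contribution", ascending=False, kind="mergesort")
    out["cum_pct"] = out["pct"].cumsum()
    return out.reset_index(drop=True)
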