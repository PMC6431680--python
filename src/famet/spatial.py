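"""Spatial-distribution statistics of mature focal adhesions.

Two point-pattern summaries describe where adhesions sit within a cell:

* **E-function** — the empirical cumulative distribution of the Euclidean
  distance from each adhesion centroid to the nucleus centroid. A straight
  line constrained through the origin is least-squares fitted to the step
  points; its slope (the *cell E-slope*, 1/µm) is large when adhesions
  concentrate near the nucleus.
* **G-function** — the set of nearest-neighbor distances among adhesion
  centroids; its per-cell mean (the *cell G-function*, µm) is small when
  adhesions are clustered.

Population-level summaries average the per-cell values within a group.
All distances are computed in the 2D projection plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class EFunction:
    """Sorted nucleus-to-adhesion distances with cumulative ranks (i+1)/n."""

    distances: np.ndarray
    cumulative_fraction: np.ndarray


@dataclass(frozen=True)
class GFunction:
    """Per-adhesion nearest-neighbor distances (µm)."""

    nn_distances: np.ndarray


def e_function(
    fa_centroids: np.ndarray, nucleus_centroid: tuple[float, float]
) -> EFunction:
    """Empirical CDF of adhesion-to-nucleus centroid distances."""
    pts = np.atleast_2d(np.asarray(fa_centroids, dtype=float))
    if pts.size == 0:
        raise ValueError("at least one adhesion centroid required")
    nuc = np.asarray(nucleus_centroid, dtype=float)
    d = np.sort(np.hypot(pts[:, 0] - nuc[0], pts[:, 1] - nuc[1]))
    n = d.size
    return EFunction(distances=d, cumulative_fraction=np.arange(1, n + 1) / n)


def e_slope(e: EFunction) -> float:
    """Zero-intercept least-squares slope over the E-function step points.

    slope = sum(d_i * f_i) / sum(d_i**2); requires a nonzero distance.
    """
    d, f = e.distances, e.cumulative_fraction
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise ValueError("E-slope undefined: all distances are zero")
    return float(np.dot(d, f) / denom)


def g_function(fa_centroids: np.ndarray) -> GFunction:
    """Exact nearest-neighbor distance for every adhesion centroid."""
    pts = np.atleast_2d(np.asarray(fa_centroids, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("G-function requires at least two adhesions")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return GFunction(nn_distances=dist[:, 1])


def cell_g(g: GFunction) -> float:
    """Cell G-function: mean nearest-neighbor distance (µm)."""
    return float(np.mean(g.nn_distances))


def population_means(
    per_cell_values: np.ndarray, groups: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Group-wise (mean, sd) of a per-cell metric.

    Sample (n-1) standard deviation; a singleton group reports sd 0.0.
    """
    values = np.asarray(per_cell_values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must have equal length")
    out: dict[str, tuple[float, float]] = {}
    for g in np.unique(groups):
        v = values[groups == g]
        if v.size == 0:
            raise ValueError(f"empty group {g!r}")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out[str(g)] = (float(np.mean(v)), sd)
    return out
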