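"""3D layouts, unit-sphere projection and surface density maps.

All spatial statistics operate on raw graphs; layouts exist purely for
per-cell visualisation. Nodes of the one-mode projection are embedded
with the Kamada-Kawai force-directed algorithm in 3D, centred and
radially projected onto the unit sphere, and marker count density over
the surface is summarised on a Fibonacci mesh with a triangular kernel
1 - d/cutoff (Euclidean chord distance), reported on a log scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .graph import ProjectedGraph

DEFAULT_GRID_POINTS = 2000
DEFAULT_DISTANCE_CUTOFF = 0.3


def layout_3d(g: ProjectedGraph, seed: int = 0) -> np.ndarray:
    """3D Kamada-Kawai coordinates for a connected projection.

    The stress optimisation starts from a deterministic initial
    placement, so the layout is reproducible; ``seed`` is accepted for
    interface stability but does not alter the result.
    """
    if g.n_nodes == 1:
        warnings.warn("single-node graph; placing at a fixed point")
        return np.array([[1.0, 0.0, 0.0]])
    if not g.is_connected():
        raise ValueError("layout requires a connected graph")
    graph = g.to_igraph()
    coords = graph.layout_kamada_kawai_3d()
    return np.asarray(coords.coords)


def sphere_project(coords: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Centre coordinates on their centroid and normalise to unit norm.

    Centering precedes normalisation so that asymmetric layouts do not
    collapse onto one hemisphere; zero-norm points are nudged by eps.
    """
    xyz = np.asarray(coords, dtype=float)
    xyz = xyz - xyz.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xyz, axis=1)
    if (norms < eps).any():
        warnings.warn("zero-norm node(s) after centering; nudging by eps")
        xyz[norms < eps] = eps
        norms = np.linalg.norm(xyz, axis=1)
    return xyz / norms[:, None]


def fibonacci_sphere(n: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Near-uniform mesh of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def density_grid(
    unit_coords: np.ndarray,
    marker_counts: np.ndarray,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Surface count density per grid point per marker.

    For each grid point, nodes within ``distance_cutoff`` (chord
    distance) contribute count * (1 - d/cutoff); the value is the
    natural log of that sum, NaN where no node is in range.

    Returns an array of shape (n_grid, n_markers).
    """
    if distance_cutoff <= 0:
        raise ValueError("distance_cutoff must be > 0")
    coords = np.asarray(unit_coords, dtype=float)
    counts = np.asarray(marker_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if grid is None:
        grid = fibonacci_sphere()
    tree = cKDTree(coords)
    values = np.full((len(grid), counts.shape[1]), np.nan)
    for gi, neighbors in enumerate(
        tree.query_ball_point(grid, r=distance_cutoff)
    ):
        if not neighbors:
            continue
        idx = np.asarray(neighbors)
        d = np.linalg.norm(coords[idx] - grid[gi], axis=1)
        w = 1.0 - d / distance_cutoff
        s = (counts[idx] * w[:, None]).sum(axis=0)
        with np.errstate(divide="ignore"):
            values[gi] = np.where(s > 0, np.log(s), np.nan)
    return values


def layout_table(
    g: ProjectedGraph,
    seed: int = 0,
) -> pd.DataFrame:
    """Layout + sphere projection as a tidy per-node table."""
    xyz = layout_3d(g, seed=seed)
    sphere = sphere_project(xyz) if g.n_nodes > 1 else xyz.copy()
    return pd.DataFrame({
        "node": g.node_ids,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "sx": sphere[:, 0], "sy": sphere[:, 1], "sz": sphere[:, 2],
    })


def density_table(
    g: ProjectedGraph,
    sphere_coords: np.ndarray,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format (grid id, marker, value) density export."""
    if grid is None:
        grid = fibonacci_sphere()
    values = density_grid(sphere_coords, g.counts,
                          distance_cutoff=distance_cutoff, grid=grid)
    frames = []
    for j, marker in enumerate(g.markers):
        frames.append(pd.DataFrame({
            "grid": np.arange(len(grid)),
            "marker": marker,
            "value": values[:, j],
        }))
    return pd.concat(frames, ignore_index=True)
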