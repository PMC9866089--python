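"""Synthetic gap-junction-coupled cardiomyocyte monolayers.

Cells are placed on a jittered hexagonal-ish grid and connected to their
Delaunay neighbours, giving a planar contact graph like a confluent
monolayer.  Each junction draws a permeability from a log-normal law around
the requested mean; each cell draws an area around the requested mean.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

import networkx as nx

from ..dye_coupling import MonolayerGraph

__all__ = ["generate_monolayer"]


def generate_monolayer(
    n_cells: int,
    *,
    mean_cell_area_um2: float = 400.0,
    cell_area_cv: float = 0.15,
    mean_permeability: float = 0.005,
    permeability_cv: float = 0.5,
    seed: int = 0,
) -> MonolayerGraph:
    """Generate a planar monolayer graph of ``n_cells`` cells.

    ``mean_permeability`` is the mean junctional rate g (1/s); set it to 0
    for a fully uncoupled sheet.  Permeabilities are log-normal with the
    given coefficient of variation (or exactly 0 when the mean is 0), areas
    normal truncated at 10 % of the mean.  Deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mean_cell_area_um2 <= 0:
        raise ValueError("mean_cell_area_um2 must be positive")
    if mean_permeability < 0:
        raise ValueError("mean_permeability must be >= 0")
    rng = np.random.default_rng(seed)

    # jittered grid: cell spacing from the mean area
    spacing = float(np.sqrt(mean_cell_area_um2))
    side = int(np.ceil(np.sqrt(n_cells)))
    jj, ii = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)[:n_cells]
    pts[:, 0] += 0.5 * (np.arange(n_cells) // side % 2)  # stagger rows
    pts *= spacing
    pts += rng.uniform(-0.2 * spacing, 0.2 * spacing, pts.shape)

    g = nx.Graph()
    areas = mean_cell_area_um2 * (1.0 + cell_area_cv * rng.standard_normal(n_cells))
    areas = np.maximum(areas, 0.1 * mean_cell_area_um2)
    for i in range(n_cells):
        g.add_node(i, area_um2=float(areas[i]), centroid=(float(pts[i, 0]), float(pts[i, 1])))

    if n_cells >= 3:
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        # drop the long spanning edges of the convex hull border
        max_len = 1.8 * spacing
        edges = {
            (i, j) for i, j in edges if np.linalg.norm(pts[i] - pts[j]) <= max_len
        }
    elif n_cells == 2:
        edges = {(0, 1)}
    else:
        edges = set()

    if mean_permeability > 0 and permeability_cv > 0:
        sigma = float(np.sqrt(np.log(1.0 + permeability_cv**2)))
        mu = float(np.log(mean_permeability)) - 0.5 * sigma**2
    for i, j in sorted(edges):
        if mean_permeability == 0:
            perm = 0.0
        elif permeability_cv > 0:
            perm = float(np.exp(rng.normal(mu, sigma)))
        else:
            perm = mean_permeability
        g.add_edge(i, j, g_per_s=perm)
    return MonolayerGraph(g)
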