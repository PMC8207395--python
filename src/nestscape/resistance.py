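"""Random-walk (commute-time) distances over resistance surfaces.

A resistance raster induces a lattice graph: one node per valid cell, edges
between neighboring cells with conductance

    c(a, b) = ((1/R_a + 1/R_b) / 2) / w,

the mean of the two cell conductances divided by the hop length w (1 for
orthogonal neighbors, sqrt(2) for diagonal ones, in cell units).  The
commute time between nodes i and j is

    C(i, j) = vol(G) * R_eff(i, j),

with vol(G) the sum of node degrees (in conductance units) of the connected
component containing the points and R_eff the two-point effective
resistance, obtained by solving the grounded graph Laplacian.  Commute time
is proportional to the circuit-theoretic resistance distance, differing only
in the volume scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .grids import Raster
from .surfaces import ResistanceSurface

__all__ = [
    "LatticeGraph",
    "DisconnectedPointsError",
    "build_graph",
    "commute_distance",
    "homogeneous_distance",
    "residualize",
    "collinearity_screen",
]


class DisconnectedPointsError(ValueError):
    """Raised when query points fall in different graph components."""


@dataclass
class LatticeGraph:
    """Sparse Laplacian of the cell-adjacency graph of a resistance raster."""

    laplacian: sparse.csr_matrix
    node_of_cell: np.ndarray  # (n_rows, n_cols), -1 where nodata
    component: np.ndarray  # component id per node
    degrees: np.ndarray  # conductance-weighted degree per node
    raster: Raster

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]

    def component_volume(self, comp_id: int) -> float:
        return float(self.degrees[self.component == comp_id].sum())


_OFFSETS_4 = ((0, 1, 1.0), (1, 0, 1.0))
_OFFSETS_8 = _OFFSETS_4 + ((1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


def build_graph(surface: ResistanceSurface | Raster, neighborhood: int = 8) -> LatticeGraph:
    """Build the conductance-weighted lattice graph of a resistance surface."""
    raster = surface.raster if isinstance(surface, ResistanceSurface) else surface
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    R = np.asarray(raster.values, dtype=float)
    valid = raster.valid_mask()
    if not valid.any():
        raise ValueError("all cells are nodata; the surface has no graph")
    if np.any(R[valid] < 1):
        raise ValueError("resistance values must be >= 1")
    n_rows, n_cols = R.shape
    node_of_cell = np.full((n_rows, n_cols), -1, dtype=np.int64)
    node_of_cell[valid] = np.arange(valid.sum())
    n = int(valid.sum())
    cond_cell = np.where(valid, 1.0 / np.where(valid, R, 1.0), 0.0)

    rows_i, rows_j, vals = [], [], []
    offsets = _OFFSETS_8 if neighborhood == 8 else _OFFSETS_4
    for dr, dc, w in offsets:
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        a = node_of_cell[r0, c0]
        b = node_of_cell[r1, c1]
        ok = (a >= 0) & (b >= 0)
        c = ((cond_cell[r0, c0] + cond_cell[r1, c1]) / 2.0 / w)[ok]
        rows_i.append(a[ok])
        rows_j.append(b[ok])
        vals.append(c)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    c = np.concatenate(vals)

    adj = sparse.coo_matrix((np.r_[c, c], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    lap = sparse.diags(degrees) - adj
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    return LatticeGraph(lap.tocsr(), node_of_cell, comp, degrees, raster)


def _points_to_nodes(graph: LatticeGraph, points: np.ndarray) -> np.ndarray:
    nodes = np.empty(len(points), dtype=np.int64)
    for k, (x, y) in enumerate(points):
        row, col = graph.raster.cell_of(float(x), float(y))
        node = graph.node_of_cell[row, col]
        if node < 0:
            raise ValueError(f"point ({x}, {y}) falls on a nodata cell")
        nodes[k] = node
    return nodes


def commute_distance(graph: LatticeGraph, points) -> np.ndarray:
    """Pairwise commute-time distances between points (map coordinates).

    Points are snapped to the center of their containing cell; co-located
    points share a node and get distance zero.  All points must lie in one
    connected component, otherwise :class:`DisconnectedPointsError` is
    raised.
    """
    points = np.asarray(points, dtype=float)
    nodes = _points_to_nodes(graph, points)
    comps = graph.component[nodes]
    if len(np.unique(comps)) > 1:
        counts = pd.Series(comps).value_counts().to_dict()
        raise DisconnectedPointsError(
            f"points fall in {len(counts)} different graph components "
            f"(component id -> n points: {counts}); commute distance is undefined"
        )
    comp_id = int(comps[0])
    in_comp = np.flatnonzero(graph.component == comp_id)
    volume = graph.component_volume(comp_id)

    # restrict the Laplacian to the component, ground one query node, and
    # solve for the potentials of the remaining query nodes
    local = -np.ones(graph.n_nodes, dtype=np.int64)
    local[in_comp] = np.arange(len(in_comp))
    L = graph.laplacian[in_comp][:, in_comp].tocsc()
    q_local = local[nodes]
    uniq, inv = np.unique(q_local, return_inverse=True)
    ground = uniq[0]
    keep = np.flatnonzero(np.arange(L.shape[0]) != ground)
    lu = splu(L[keep][:, keep])
    pos = -np.ones(L.shape[0], dtype=np.int64)
    pos[keep] = np.arange(len(keep))

    m = len(uniq)
    X = np.zeros((m, m))
    sols = {}
    for a in range(1, m):
        e = np.zeros(len(keep))
        e[pos[uniq[a]]] = 1.0
        sols[a] = lu.solve(e)
    for a in range(1, m):
        for b in range(1, m):
            X[a, b] = sols[a][pos[uniq[b]]]

    reff_u = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            reff_u[a, b] = X[a, a] + X[b, b] - 2 * X[a, b]
    reff = reff_u[np.ix_(inv, inv)]
    C = volume * reff
    np.fill_diagonal(C, 0.0)
    return (C + C.T) / 2.0


def homogeneous_distance(points, template: Raster, neighborhood: int = 8) -> np.ndarray:
    """Commute distance over a uniform resistance-1 surface with the
    geometry of ``template`` — the straight-line-distance analogue used to
    residualize landscape predictors."""
    ones = template.like(np.ones(template.values.shape), nodata=None)
    mask = template.valid_mask()
    if not mask.all():
        vals = np.where(mask, 1.0, np.nan)
        ones = template.like(vals)
    graph = build_graph(ones, neighborhood=neighborhood)
    return commute_distance(graph, points)


def residualize(predictor: np.ndarray, homogeneous: np.ndarray) -> np.ndarray:
    """Residuals of an OLS fit of a predictor column on the homogeneous
    (uniform-landscape) distance column, with intercept.

    Removes the straight-line geographic-distance component so the residual
    carries only the landscape signal of the predictor.
    """
    predictor = np.asarray(predictor, dtype=float)
    homogeneous = np.asarray(homogeneous, dtype=float)
    if predictor.shape != homogeneous.shape:
        raise ValueError("predictor and homogeneous columns differ in length")
    if np.ptp(homogeneous) == 0:
        raise ValueError("homogeneous distance column is constant; cannot residualize")
    A = np.column_stack([np.ones_like(homogeneous), homogeneous])
    coef, *_ = np.linalg.lstsq(A, predictor, rcond=None)
    return predictor - A @ coef


def collinearity_screen(
    predictors: pd.DataFrame,
    threshold: float = 0.5,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop redundant predictor classes by pairwise Pearson correlation.

    Classes are scanned in priority order (default: column order); a class is
    retained only if its |r| with every already-retained class does not
    exceed the threshold.  Returns the retained class names and the full
    correlation matrix.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least two predictor columns to screen")
    order = list(priority) if priority is not None else list(predictors.columns)
    missing = set(order) - set(predictors.columns)
    if missing:
        raise KeyError(f"priority names not in predictors: {sorted(missing)}")
    corr = predictors.corr(method="pearson")
    retained: list[str] = []
    for cls in order:
        if all(abs(corr.loc[cls, kept]) <= threshold for kept in retained):
            retained.append(cls)
    return retained, corr
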