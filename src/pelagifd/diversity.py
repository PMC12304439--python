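"""Biomass-weighted functional diversity indices in PCoA space.

Four complementary indices describe how an assemblage fills functional
space (Villeger-style kernels):

* FRic — volume of the convex hull of the species present (also reported
  as a fraction of the whole-community hull);
* FEve — regularity of biomass along the minimum spanning tree linking the
  species;
* FDis — biomass-weighted mean distance to the biomass-weighted centroid;
* FDiv — degree to which biomass sits on species far from the centre of
  gravity of the hull vertices.

Weights are relative biomasses and must sum to one. The ``*_points``
kernels operate on bare coordinate arrays (as needed by the trait-
randomisation null model); :func:`compute_indices` is the labelled wrapper
used on real assemblages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import DimensionalityError, UndefinedIndexError
from .space import FunctionalSpace

logger = logging.getLogger(__name__)

__all__ = [
    "FDIndices",
    "hull_volume_points",
    "fric_points",
    "feve_points",
    "fdis_points",
    "fdiv_points",
    "fdis_batch",
    "compute_indices",
]


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {w.sum():.6f}")
    return w


def hull_volume_points(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Convex-hull volume and vertex row indices of a point set.

    Coincident rows (e.g. duplicate species drawn by the null model) are
    deduplicated first; every input row lying on a vertex position is
    reported as a vertex.
    """
    pts = np.asarray(pts, dtype=float)
    m = pts.shape[1]
    uniq, inverse = np.unique(np.round(pts, 12), axis=0, return_inverse=True)
    if len(uniq) < m + 1:
        raise DimensionalityError(
            f"{len(uniq)} distinct points cannot span a {m}-D hull"
        )
    try:
        hull = ConvexHull(uniq)
    except QhullError as exc:
        raise DimensionalityError(f"degenerate {m}-D point set: {exc}") from exc
    vertex_rows = np.isin(inverse, hull.vertices).nonzero()[0]
    return float(hull.volume), vertex_rows


def fric_points(pts: np.ndarray) -> float:
    """Convex-hull volume (functional richness, unscaled)."""
    return hull_volume_points(pts)[0]


def feve_points(pts: np.ndarray, weights) -> float:
    """Functional evenness along the minimum spanning tree.

    Each MST edge (i, j) is valued EW = dist(i, j) / (w_i + w_j) and
    normalised to partial weights PEW = EW / sum(EW); FEve rescales the
    sum of min(PEW, 1/(S-1)) to [0, 1], where 1 means perfectly regular
    spacing and weighting.
    """
    pts = np.asarray(pts, dtype=float)
    w = _check_weights(weights)
    S = len(pts)
    if S < 3:
        raise UndefinedIndexError(f"FEve needs >= 3 species, got {S}")
    dist = squareform(pdist(pts))
    mst = minimum_spanning_tree(dist).tocoo()
    if len(mst.data) < S - 1:
        # zero-length edges dropped by the sparse representation: rebuild
        # with a small positive floor so the tree stays connected
        floor = dist[dist > 0].min() * 1e-9 if (dist > 0).any() else 1.0
        mst = minimum_spanning_tree(np.maximum(dist, floor)).tocoo()
        edge_d = dist[mst.row, mst.col]
    else:
        edge_d = mst.data
    ew = edge_d / (w[mst.row] + w[mst.col])
    if ew.sum() == 0:
        return 1.0  # all species coincident: trivially even
    pew = ew / ew.sum()
    thr = 1.0 / (S - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def fdis_points(pts: np.ndarray, weights) -> float:
    """Biomass-weighted mean distance to the biomass-weighted centroid."""
    pts = np.asarray(pts, dtype=float)
    w = _check_weights(weights)
    centroid = w @ pts
    return float(w @ np.linalg.norm(pts - centroid, axis=1))


def fdis_batch(pts: np.ndarray, weights) -> np.ndarray:
    """FDis for a batch of assemblages, shape (n, S, m) -> (n,)."""
    pts = np.asarray(pts, dtype=float)
    w = _check_weights(weights)
    centroid = np.einsum("s,nsm->nm", w, pts)
    dist = np.linalg.norm(pts - centroid[:, None, :], axis=2)
    return dist @ w


def fdiv_points(pts: np.ndarray, weights) -> float:
    """Functional divergence.

    With G the unweighted centre of gravity of the hull vertices and dG_i
    each species' distance to G: FDiv = (delta_d + mean_dG) /
    (delta_abs_d + mean_dG), where delta_d (resp. delta_abs_d) is the
    biomass-weighted sum of (dG_i - mean_dG) (resp. its absolute value).
    Values near 1 indicate biomass concentrated far from G.
    """
    pts = np.asarray(pts, dtype=float)
    w = _check_weights(weights)
    _, vertex_rows = hull_volume_points(pts)
    G = pts[vertex_rows].mean(axis=0)
    dG = np.linalg.norm(pts - G, axis=1)
    mean_dG = dG.mean()
    delta_d = float(w @ (dG - mean_dG))
    delta_abs = float(w @ np.abs(dG - mean_dG))
    if delta_abs + mean_dG == 0:
        return 1.0
    return (delta_d + mean_dG) / (delta_abs + mean_dG)


@dataclass
class FDIndices:
    """The four indices for one assemblage, with the hull dimension used."""

    fric: float
    fric_fraction: float
    feve: float
    fdis: float
    fdiv: float
    m_used: int
    flags: list[str]


def feasible_hull_dim(pts: np.ndarray, m: int) -> int:
    """Largest m' <= m for which the points span an m'-dimensional hull."""
    n_unique = len(np.unique(np.round(np.asarray(pts), 12), axis=0))
    m_used = min(m, n_unique - 1)
    while m_used >= 2:
        try:
            hull_volume_points(np.asarray(pts)[:, :m_used])
            return m_used
        except DimensionalityError:
            m_used -= 1
    raise DimensionalityError("point set too degenerate for any hull")


def compute_indices(
    space: FunctionalSpace,
    species: list[str],
    weights,
    m: int | None = None,
    community_volume: float | None = None,
) -> FDIndices:
    """All four indices for one labelled assemblage.

    Species are processed in sorted label order so MST ties resolve
    deterministically. Assemblages too species-poor for the requested hull
    dimensionality fall back to the largest feasible one (flagged), so
    FRic/FDiv remain defined for layers with few species.
    """
    m = space.m if m is None else m
    w = _check_weights(weights)
    order = np.argsort(np.asarray(species, dtype=object), kind="stable")
    labels = [species[i] for i in order]
    w = w[order]
    pts = space.coordinates.loc[labels].to_numpy()[:, :m]
    flags: list[str] = []
    m_used = feasible_hull_dim(pts, m)
    if m_used < m:
        flags.append(f"hull dimensionality reduced to {m_used}")
        logger.warning(
            "assemblage of %d species: hull dimensionality reduced to %d",
            len(labels),
            m_used,
        )
    volume = fric_points(pts[:, :m_used])
    fraction = np.nan if community_volume is None else volume / community_volume
    return FDIndices(
        fric=volume,
        fric_fraction=fraction,
        feve=feve_points(pts, w),
        fdis=fdis_points(pts, w),
        fdiv=fdiv_points(pts[:, :m_used], w),
        m_used=m_used,
        flags=flags,
    )
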