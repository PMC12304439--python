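"""Functional space: Gower dissimilarity, PCoA embedding, quality, hull.

Species are placed in a multidimensional functional space by (i) computing
a Gower dissimilarity matrix over the mixed continuous/ordinal/binary trait
matrix, (ii) embedding it by principal coordinates analysis, (iii) scoring
candidate dimensionalities by the mean squared deviation between trait-based
and embedded distances, and (iv) identifying the convex-hull vertex species
that carry the most extreme trait combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateSpaceError, DimensionalityError
from .traits import TRAIT_KINDS

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalSpace",
    "HullResult",
    "gower",
    "pcoa",
    "space_quality",
    "quality_profile",
    "hull_vertices",
]


def gower(
    matrix: pd.DataFrame, kinds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Gower dissimilarity over a mixed-type species x trait matrix.

    d_ij = mean over traits of a per-trait dissimilarity delta in [0, 1],
    with equal weights: continuous traits use the range-normalised absolute
    difference; ordinal traits are first converted to tie-averaged ranks
    (Podani's convention) and then treated as continuous; binary traits use
    simple matching (0 iff equal). A constant column has no information and
    contributes delta = 0 for every pair (with a warning) while keeping its
    unit weight in the denominator.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 species")
    if matrix.isna().any().any():
        raise ValueError("trait matrix must be complete")
    kinds = kinds or TRAIT_KINDS
    n = len(matrix)
    total = np.zeros((n, n))
    informative = 0
    for col in matrix.columns:
        kind = kinds.get(col, "continuous")
        x = matrix[col].to_numpy(dtype=float)
        if kind == "binary":
            delta = (x[:, None] != x[None, :]).astype(float)
            if np.all(x == x[0]):
                logger.warning("constant binary column %r contributes 0", col)
            else:
                informative += 1
        else:
            if kind == "ordinal":
                x = rankdata(x)  # tie-averaged ranks, then range-scaled
            rng = np.ptp(x)
            if rng == 0:
                logger.warning("constant column %r contributes 0", col)
                delta = np.zeros((n, n))
            else:
                delta = np.abs(x[:, None] - x[None, :]) / rng
                informative += 1
        total += delta
    if informative == 0:
        raise DegenerateSpaceError("all trait columns are constant")
    D = total / matrix.shape[1]
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class FunctionalSpace:
    """PCoA embedding: species coordinates, eigenvalues, quality profile."""

    coordinates: pd.DataFrame  # species x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # sorted descending, positive ones retained
    proportion_explained: np.ndarray  # over positive eigenvalues, sums to 1
    correction: str
    negative_eigenvalue_warning: bool = False
    quality: dict[int, float] = field(default_factory=dict)
    m: int = 4
    #: dissimilarities actually embedded (post-correction); the quality
    #: score compares projections against these
    embedded_dissimilarities: pd.DataFrame | None = None

    @property
    def species(self) -> pd.Index:
        return self.coordinates.index

    def axes(self, m: int | None = None) -> np.ndarray:
        m = self.m if m is None else m
        return self.coordinates.to_numpy()[:, :m]


def _gower_centering(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _cailliez_constant(D: np.ndarray) -> float:
    # Smallest c such that D + c (off-diagonal) is Euclidean-embeddable:
    # largest real eigenvalue of the standard 2n x 2n block matrix.
    n = D.shape[0]
    delta1 = _gower_centering(D)  # -1/2 J D^2 J
    J = np.eye(n) - np.ones((n, n)) / n
    delta2 = -0.5 * J @ D @ J
    block = np.block(
        [[np.zeros((n, n)), 2 * delta1], [-np.eye(n), -4 * delta2]]
    )
    eigs = scipy.linalg.eigvals(block)
    return float(np.max(eigs.real))


def pcoa(
    D: pd.DataFrame,
    correction: str = "sqrt",
    negative_tol: float = 1e-8,
) -> FunctionalSpace:
    """Principal coordinates analysis of a dissimilarity matrix.

    Double-centres -1/2 D^2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. If negative
    eigenvalues exceed `negative_tol` relative to the largest positive one,
    the configured correction is applied first: "sqrt" replaces d by
    sqrt(d) (Euclidean-embeddable for Gower dissimilarities), "cailliez"
    adds the Cailliez constant to off-diagonal entries, "none" proceeds and
    records a warning on the result. Percent variation per axis is computed
    over positive eigenvalues only.
    """
    if correction not in ("none", "sqrt", "cailliez"):
        raise ConfigError(f"unknown correction {correction!r}")
    labels = D.index
    A = np.asarray(D, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("D must be a square symmetric matrix")

    def _decompose(mat: np.ndarray):
        eigval, eigvec = scipy.linalg.eigh(_gower_centering(mat))
        order = np.argsort(eigval)[::-1]
        return eigval[order], eigvec[:, order]

    eigval, eigvec = _decompose(A)
    applied = "none"
    warned = False
    if eigval[-1] < -negative_tol * max(eigval[0], 1.0):
        if correction == "sqrt":
            A = np.sqrt(A)
            eigval, eigvec = _decompose(A)
            applied = "sqrt"
        elif correction == "cailliez":
            c = _cailliez_constant(A)
            A = A + c * (1 - np.eye(len(A)))
            eigval, eigvec = _decompose(A)
            applied = "cailliez"
        else:
            warned = True
            logger.warning(
                "negative PCoA eigenvalues left uncorrected (min %.3g)",
                eigval[-1],
            )
    pos = eigval > negative_tol * max(eigval[0], 1.0)
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    coord_df = pd.DataFrame(
        coords,
        index=labels,
        columns=[f"pcoa_{i + 1}" for i in range(coords.shape[1])],
    )
    return FunctionalSpace(
        coordinates=coord_df,
        eigenvalues=lam,
        proportion_explained=lam / lam.sum(),
        correction=applied,
        negative_eigenvalue_warning=warned,
        embedded_dissimilarities=pd.DataFrame(A, index=labels, columns=labels),
    )


def space_quality(D: pd.DataFrame, space: FunctionalSpace, m: int) -> float:
    """Mean squared deviation between trait and embedded distances (mSD).

    Euclidean distances on the first m axes are rescaled so their maximum
    equals the maximum trait-based dissimilarity, then mSD is the mean over
    unordered pairs of the squared deviation. Lower is better; an exact
    embedding scores 0 and nested projections never worsen the score.
    When the space was built on corrected dissimilarities the comparison
    targets those (the quantities the axes actually reproduce).
    """
    if m < 2:
        raise ConfigError("m must be >= 2")
    if m > space.coordinates.shape[1]:
        raise ConfigError(
            f"m={m} exceeds available axes ({space.coordinates.shape[1]})"
        )
    target = (
        space.embedded_dissimilarities
        if space.embedded_dissimilarities is not None
        else D
    )
    d = squareform(np.asarray(target, dtype=float), checks=False)
    s = pdist(space.axes(m))
    if s.max() > 0:
        s = s * (d.max() / s.max())
    return float(np.mean((s - d) ** 2))


def quality_profile(
    D: pd.DataFrame, space: FunctionalSpace, m_max: int = 10
) -> dict[int, float]:
    """mSD for each candidate dimensionality m = 2..min(S-1, m_max, axes)."""
    upper = min(len(D) - 1, m_max, space.coordinates.shape[1])
    profile = {m: space_quality(D, space, m) for m in range(2, upper + 1)}
    space.quality = profile
    return profile


@dataclass
class HullResult:
    """Convex hull of species points: vertex identities and volume."""

    vertices: list[str]
    non_vertices: list[str]
    volume: float
    m: int


def hull_vertices(
    space: FunctionalSpace,
    species: list[str] | None = None,
    m: int | None = None,
) -> HullResult:
    """Convex hull (Qhull) of the selected species in the first m axes.

    Coincident points are deduplicated before the hull is built; all labels
    sharing a vertex position are reported as vertices. Degenerate sets
    (fewer than m+1 affinely independent points) raise a
    DimensionalityError naming the assemblage.
    """
    m = space.m if m is None else m
    labels = list(space.species) if species is None else list(species)
    pts = space.coordinates.loc[labels].to_numpy()[:, :m]
    uniq, inverse = np.unique(np.round(pts, 12), axis=0, return_inverse=True)
    if len(uniq) < m + 1:
        raise DimensionalityError(
            f"{len(uniq)} distinct points cannot span a {m}-D hull "
            f"(assemblage of {labels[:3]}...)"
        )
    try:
        hull = ConvexHull(uniq)
    except QhullError as exc:
        raise DimensionalityError(
            f"degenerate point set for {m}-D hull: {exc}"
        ) from exc
    vertex_rows = set(hull.vertices)
    vertices = [lab for lab, row in zip(labels, inverse) if row in vertex_rows]
    non_vertices = [lab for lab in labels if lab not in set(vertices)]
    return HullResult(
        vertices=vertices,
        non_vertices=non_vertices,
        volume=float(hull.volume),
        m=m,
    )
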