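"""Trait-randomisation null model and standardised effect sizes (SES).

The null hypothesis is that species traits are independent of their
ecological (depth) distribution. For an assemblage of S species, each null
draw resamples S whole trait vectors — equivalently functional-space
coordinate rows — with replacement from the full species pool, keeping the
observed biomass weights in slot order. Whole-row resampling preserves the
trait covariance structure (the standard trait-swap null); an optional
per-trait mode shuffles each axis independently instead.

Each diversity index observed in an assemblage is compared with its 999
null values through SES = (obs - mean_null) / sd_null. Significance
follows a two-branch rule: when the null values are normal (Shapiro-Wilk,
raw or after log transform), |SES| > 1.96 is significant; otherwise the
observed value is compared with the 2.5% and 97.5% percentiles of the null
distribution. Negative SES indicates trait convergence (environmental
filtering), positive SES trait divergence (limiting similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import (
    fdis_batch,
    fdis_points,
    fdiv_points,
    feasible_hull_dim,
    feve_points,
    fric_points,
)
from .errors import DegenerateNullError
from .space import FunctionalSpace

logger = logging.getLogger(__name__)

__all__ = [
    "SESResult",
    "randomize_traits",
    "ses",
    "assess_distribution",
    "significance",
    "null_model_ses",
]

INDEX_NAMES = ("fric", "feve", "fdis", "fdiv")


def randomize_traits(
    pool_size: int,
    richness: int,
    n_sim: int,
    rng: np.random.Generator,
    per_trait: bool = False,
    n_traits: int | None = None,
) -> np.ndarray:
    """Null-model draw indices into the species pool.

    Whole-row mode (default) returns an (n_sim, richness) array of pool row
    indices drawn with replacement: each assemblage slot receives a whole
    trait vector. Per-trait mode returns (n_sim, richness, n_traits) with
    every trait column drawn independently, breaking trait covariance.
    """
    if pool_size < 1:
        raise ValueError("empty species pool")
    if per_trait:
        if n_traits is None:
            raise ValueError("per_trait mode needs n_traits")
        return rng.integers(0, pool_size, size=(n_sim, richness, n_traits))
    return rng.integers(0, pool_size, size=(n_sim, richness))


def ses(observed: float, simulated: np.ndarray) -> float:
    """Standardised effect size: (obs - mean(null)) / sd(null), sd with
    the n-1 denominator."""
    sim = np.asarray(simulated, dtype=float)
    if sim.size < 2:
        raise ValueError("need >= 2 simulated values")
    sd = sim.std(ddof=1)
    if sd == 0:
        raise DegenerateNullError("null distribution has zero spread")
    return float((observed - sim.mean()) / sd)


def assess_distribution(
    simulated: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float, str]:
    """Normality and symmetry screen of a null distribution.

    Shapiro-Wilk at `alpha`; if rejected and all values are positive the
    values are log-transformed and retested. Returns (normal, skewness,
    transform) with the adjusted Fisher-Pearson skewness computed on the
    working (possibly log) scale; |skewness| > 1 is flagged as largely
    asymmetric by callers.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.size < 3:
        raise ValueError("need >= 3 simulated values")
    if np.ptp(sim) == 0:
        return False, 0.0, "none"
    p = stats.shapiro(sim).pvalue
    if p >= alpha:
        return True, float(stats.skew(sim, bias=False)), "none"
    if np.all(sim > 0):
        log_sim = np.log(sim)
        p_log = stats.shapiro(log_sim).pvalue
        skew_log = float(stats.skew(log_sim, bias=False))
        if p_log >= alpha:
            return True, skew_log, "log"
        return False, skew_log, "log"
    return False, float(stats.skew(sim, bias=False)), "none"


@dataclass
class SESResult:
    """SES of one index in one assemblage, with its significance pathway."""

    index: str
    observed: float
    mean_sim: float
    sd_sim: float
    ses: float
    shapiro_p: float
    skewness: float
    transform: str
    pathway: str  # "gaussian" | "percentile"
    significant: bool
    p025: float
    p975: float
    n_sim: int
    largely_asymmetric: bool = False
    null_values: np.ndarray | None = field(default=None, repr=False)


def significance(
    index: str,
    observed: float,
    simulated: np.ndarray,
    alpha: float = 0.05,
    z_threshold: float = 1.96,
    keep_null: bool = False,
) -> SESResult:
    """SES with the normality/skewness/percentile decision tree.

    Gaussian pathway (null normal on the raw or log scale): significant
    iff the working-scale |SES| exceeds `z_threshold`. Percentile pathway
    otherwise: significant iff the observed value falls outside the
    [2.5%, 97.5%] interval of the null values (linear-interpolation
    percentiles; monotone transforms do not change this comparison).
    The reported SES is always on the raw index scale.
    """
    sim = np.asarray(simulated, dtype=float)
    raw_ses = ses(observed, sim)
    normal, skewness, transform = assess_distribution(sim, alpha=alpha)
    shapiro_p = float(stats.shapiro(np.log(sim) if transform == "log" else sim).pvalue)
    p025, p975 = np.percentile(sim, [2.5, 97.5])
    if normal:
        if transform == "log":
            if observed <= 0:
                working_ses = -np.inf
            else:
                working_ses = ses(np.log(observed), np.log(sim))
        else:
            working_ses = raw_ses
        pathway = "gaussian"
        significant = abs(working_ses) > z_threshold
    else:
        pathway = "percentile"
        significant = bool(observed < p025 or observed > p975)
    return SESResult(
        index=index,
        observed=float(observed),
        mean_sim=float(sim.mean()),
        sd_sim=float(sim.std(ddof=1)),
        ses=raw_ses,
        shapiro_p=shapiro_p,
        skewness=skewness,
        transform=transform,
        pathway=pathway,
        significant=significant,
        p025=float(p025),
        p975=float(p975),
        n_sim=int(sim.size),
        largely_asymmetric=abs(skewness) > 1.0,
        null_values=sim if keep_null else None,
    )


def null_model_ses(
    space: FunctionalSpace,
    species: list[str],
    weights,
    n_sim: int = 999,
    seed: int | None = None,
    indices: tuple[str, ...] = INDEX_NAMES,
    m: int | None = None,
    alpha: float = 0.05,
    z_threshold: float = 1.96,
    per_trait: bool = False,
    keep_null: bool = False,
) -> dict[str, SESResult]:
    """SES of the requested indices for one assemblage.

    Null draws resample coordinate rows with replacement from the *full*
    species pool held by `space` (traits independent of depth), keeping
    the observed biomass weights fixed in slot order. Hull-based indices
    in null assemblages fall back to a feasible dimensionality when
    duplicate draws make the point set degenerate.
    """
    m = space.m if m is None else m
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    S = len(species)
    pool_pts = space.coordinates.to_numpy()[:, :m]
    obs_pts = space.coordinates.loc[list(species)].to_numpy()[:, :m]
    rng = np.random.default_rng(seed)
    draws = randomize_traits(
        len(pool_pts), S, n_sim, rng, per_trait=per_trait, n_traits=m
    )
    if per_trait:
        sim_pts = pool_pts[draws, np.arange(m)[None, None, :]]
    else:
        sim_pts = pool_pts[draws]  # (n_sim, S, m)

    results: dict[str, SESResult] = {}
    needs_loop = [i for i in indices if i != "fdis"]
    sims: dict[str, np.ndarray] = {i: np.empty(n_sim) for i in needs_loop}
    if "fdis" in indices:
        sims["fdis"] = fdis_batch(sim_pts, w)
    def _hull_indexed(func, pts, *args):
        # full dimensionality first; reduce only for degenerate draws
        try:
            return func(pts, *args)
        except DimensionalityError:
            m_fall = feasible_hull_dim(pts, m)
            return func(pts[:, :m_fall], *args)

    for s_idx in range(n_sim):
        pts = sim_pts[s_idx]
        for name in needs_loop:
            if name == "fric":
                sims[name][s_idx] = _hull_indexed(fric_points, pts)
            elif name == "feve":
                sims[name][s_idx] = feve_points(pts, w)
            elif name == "fdiv":
                sims[name][s_idx] = _hull_indexed(fdiv_points, pts, w)
            else:
                raise ValueError(f"unknown index {name!r}")
    observed = {
        "fric": lambda: fric_points(obs_pts[:, : feasible_hull_dim(obs_pts, m)]),
        "feve": lambda: feve_points(obs_pts, w),
        "fdis": lambda: fdis_points(obs_pts, w),
        "fdiv": lambda: fdiv_points(obs_pts[:, : feasible_hull_dim(obs_pts, m)], w),
    }
    for name in indices:
        results[name] = significance(
            name,
            observed[name](),
            sims[name],
            alpha=alpha,
            z_threshold=z_threshold,
            keep_null=keep_null,
        )
    return results


def ses_table(results: dict[str, dict[str, SESResult]]) -> pd.DataFrame:
    """Tidy one-row-per-(assemblage, index) table of SES results."""
    rows = []
    for assemblage, by_index in results.items():
        for name, r in by_index.items():
            rows.append(
                {
                    "assemblage": assemblage,
                    "index": name,
                    "observed": r.observed,
                    "mean_sim": r.mean_sim,
                    "sd_sim": r.sd_sim,
                    "ses": r.ses,
                    "shapiro_p": r.shapiro_p,
                    "skewness": r.skewness,
                    "transform": r.transform,
                    "pathway": r.pathway,
                    "significant": r.significant,
                    "p025": r.p025,
                    "p975": r.p975,
                    "n_sim": r.n_sim,
                }
            )
    return pd.DataFrame(rows)
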