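"""Community-weighted trait means with individual-level bootstrap, and the
PCA of layer-median CWM profiles.

The CWM of a trait in an assemblage is its biomass-weighted mean over the
species present. To propagate intraspecific variability, the point estimate
is complemented by a nonparametric bootstrap that resamples *individual*
trait values with replacement, selecting individuals in proportion to their
species' biomass at that sampling depth (depth-specific individuals when
available, the species-wide pool otherwise). The two nominal-use ordinal
traits (gill raker type, oral gape axis) are excluded; binary traits yield
biomass-weighted proportions present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .traits import BINARY_TRAITS, CONTINUOUS_TRAITS, TRAIT_KINDS

logger = logging.getLogger(__name__)

__all__ = [
    "CWM_TRAITS",
    "CWMDistribution",
    "cwm_point",
    "cwm_bootstrap",
    "cwm_pca",
]

#: Traits entering CWM: all but the two nominal-use ordinal traits.
CWM_TRAITS = CONTINUOUS_TRAITS + BINARY_TRAITS


def cwm_point(trait_values: pd.Series, weights: pd.Series) -> float:
    """Biomass-weighted mean of one trait over the species present.

    `trait_values` and `weights` are indexed by species; weights are
    renormalised over the species whose trait value is observed. Returns
    NaN when the trait is missing for every present species.
    """
    joined = pd.concat([trait_values, weights], axis=1, keys=["t", "w"]).dropna()
    if joined.empty:
        return np.nan
    w = joined["w"] / joined["w"].sum()
    return float((joined["t"] * w).sum())


@dataclass
class CWMDistribution:
    """Bootstrap distribution of the CWM of one trait at one depth."""

    trait: str
    depth: float
    boot_means: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    sample_size: int


def cwm_bootstrap(
    individuals: pd.DataFrame,
    biomass: pd.Series,
    trait: str,
    depth: float | None = None,
    n_boot: int = 999,
    sample_size: int = 200,
    seed: int | None = None,
    depth_window: float | None = None,
) -> CWMDistribution:
    """Bootstrap the CWM of `trait` at one sampling depth.

    `individuals` is an individual x trait table with a `species` column
    (and `capture_depth` if depth-specific pools are wanted); `biomass`
    maps the species present at this depth to their biomass. Each of the
    `n_boot` draws samples `sample_size` individuals with replacement,
    picking species in proportion to biomass and individuals uniformly
    within species; the draw statistic is the mean trait value. Species
    with biomass but no measured individuals anywhere are excluded with a
    log message. When `depth_window` is given, a species' pool is narrowed
    to individuals captured within +/- window of `depth` when any exist.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, np.ndarray] = {}
    masses: dict[str, float] = {}
    for species, mass in biomass.items():
        if mass <= 0:
            continue
        subset = individuals[individuals["species"] == species]
        if depth_window is not None and depth is not None and len(subset):
            near = subset[
                (subset["capture_depth"] - depth).abs() <= depth_window
            ]
            if len(near):
                subset = near
        values = subset[trait].dropna().to_numpy(dtype=float)
        if values.size == 0:
            logger.info(
                "species %s has biomass at depth %s but no measured "
                "individuals for %s; excluded",
                species,
                depth,
                trait,
            )
            continue
        pools[species] = values
        masses[species] = float(mass)
    if not pools:
        raise ValueError(f"no measurable species for trait {trait!r}")
    names = sorted(pools)
    # flatten to one individual-level pool: picking a species with
    # probability ~ biomass and an individual uniformly within it is the
    # same as picking individuals with probability biomass / pool size
    values = np.concatenate([pools[s] for s in names])
    probs = np.concatenate(
        [np.full(len(pools[s]), masses[s] / len(pools[s])) for s in names]
    )
    probs = probs / probs.sum()
    # inverse-CDF sampling: much faster than Generator.choice with p
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    draws = np.searchsorted(cum, rng.random((n_boot, sample_size)), side="right")
    boot = values[draws].mean(axis=1)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return CWMDistribution(
        trait=trait,
        depth=np.nan if depth is None else float(depth),
        boot_means=boot,
        mean=float(boot.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        sample_size=sample_size,
    )


def cwm_pca(
    layer_medians: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the layer x trait matrix of median CWM values.

    Columns are centred and scaled to unit variance (constant columns
    dropped with a warning), so the decomposition is of the correlation
    structure. Returns (loadings, scores, percent variance); with L layers
    at most L-1 components are non-null and their percent variances sum
    to 100.
    """
    if layer_medians.shape[0] < 2 or layer_medians.shape[1] < 2:
        raise ValueError("need >= 2 layers and >= 2 traits")
    if layer_medians.isna().any().any():
        raise ValueError("layer-median CWM matrix must be complete")
    X = layer_medians.copy()
    constant = X.columns[X.std(ddof=0) == 0]
    if len(constant):
        logger.warning("dropping constant CWM columns: %s", list(constant))
        X = X.drop(columns=constant)
    Z = (X - X.mean()) / X.std(ddof=1)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.to_numpy())
    pct = 100 * pca.explained_variance_ratio_
    comp_names = [f"pc_{i + 1}" for i in range(n_comp)]
    loadings = pd.DataFrame(pca.components_.T, index=X.columns, columns=comp_names)
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp_names)
    return loadings, scores_df, pct
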