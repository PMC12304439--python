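"""Functional rarity: trait uniqueness and depth-range restrictedness.

Uniqueness U_i is the smallest Gower dissimilarity between species i and
any other community member: high values mark species whose trait
combination has no close analogue. Restrictedness R_i is one minus the
fraction of the sampled depth extent a species occupies: R = 0 for a
species spanning the whole 20-2000 m column, R -> 1 for a species confined
to a narrow band. Species combining high U and high R are the community's
functionally rarest members.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["uniqueness", "restrictedness", "rarity_table"]


def uniqueness(D: pd.DataFrame) -> pd.Series:
    """U_i = min_{j != i} d_ij for every species of a dissimilarity matrix."""
    if len(D) < 2:
        raise ValueError("need >= 2 species")
    A = np.asarray(D, dtype=float).copy()
    np.fill_diagonal(A, np.inf)
    return pd.Series(A.min(axis=1), index=D.index, name="uniqueness")


def restrictedness(
    occurrence_depths: dict[str, tuple[float, float]] | pd.DataFrame,
    depth_min: float = 20.0,
    depth_max: float = 2000.0,
) -> pd.Series:
    """R_i = 1 - (species depth extent) / (total sampled extent), in [0, 1].

    `occurrence_depths` maps species to (shallowest, deepest) occurrence,
    or is a DataFrame with depth_min_m/depth_max_m columns indexed or
    keyed by species. A species observed at a single depth has zero extent
    and is flagged with R = 1.
    """
    if isinstance(occurrence_depths, pd.DataFrame):
        df = occurrence_depths
        if "species" in df.columns:
            df = df.set_index("species")
        ranges = {
            sp: (float(row["depth_min_m"]), float(row["depth_max_m"]))
            for sp, row in df.iterrows()
        }
    else:
        ranges = occurrence_depths
    total = depth_max - depth_min
    if total <= 0:
        raise ValueError("total sampled extent must be positive")
    out = {}
    for sp, (lo, hi) in ranges.items():
        extent = hi - lo
        if extent == 0:
            logger.warning(
                "species %s observed at a single depth; restrictedness = 1", sp
            )
        out[sp] = float(np.clip(1.0 - extent / total, 0.0, 1.0))
    return pd.Series(out, name="restrictedness")


def rarity_table(D: pd.DataFrame, occurrence_depths, **kwargs) -> pd.DataFrame:
    """Per-species uniqueness, restrictedness, and above-median flags."""
    U = uniqueness(D)
    R = restrictedness(occurrence_depths, **kwargs)
    table = pd.concat([U, R], axis=1).dropna()
    table["unique_above_median"] = table["uniqueness"] > table["uniqueness"].median()
    table["restricted_above_median"] = (
        table["restrictedness"] > table["restrictedness"].median()
    )
    return table
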