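"""Trawl-haul ingestion: biomass standardisation, depth layers, assemblage tables.

Night-time midwater hauls are towed horizontally at a fixed immersion depth,
so each haul samples one depth. Catch mass per species is standardised by
the volume of water filtered (vertical opening x horizontal opening x
distance trawled, all in metres) to a biomass density in kg m^-3. Hauls are
binned into four depth layers — epipelagic, upper mesopelagic, lower
mesopelagic, bathypelagic — partitioning the 20-2000 m sampled range, and
aggregated into an assemblage x species biomass table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DepthRangeError, InvalidCatchError, InvalidGearError

logger = logging.getLogger(__name__)

__all__ = [
    "HaulRecord",
    "LayerDefinition",
    "DEFAULT_LAYERS",
    "TRAWL_SPEED_KN",
    "TRAWL_DURATION_H",
    "standardize_biomass",
    "assign_layer",
    "build_assemblages",
    "read_hauls",
]

#: Nominal towing protocol: 1 h at 4 kn, used to derive distance when absent.
TRAWL_SPEED_KN = 4.0
TRAWL_DURATION_H = 1.0
_METERS_PER_NM = 1852.0


@dataclass(frozen=True)
class LayerDefinition:
    """Half-open depth interval [depth_min, depth_max); deepest layer closed."""

    name: str
    depth_min: float
    depth_max: float

    def __post_init__(self) -> None:
        if not self.depth_min < self.depth_max:
            raise ValueError(f"layer {self.name}: depth_min must be < depth_max")


#: The four layers partitioning the 20-2000 m sampled water column.
DEFAULT_LAYERS: tuple[LayerDefinition, ...] = (
    LayerDefinition("epipelagic", 20.0, 175.0),
    LayerDefinition("upper_mesopelagic", 175.0, 700.0),
    LayerDefinition("lower_mesopelagic", 700.0, 1000.0),
    LayerDefinition("bathypelagic", 1000.0, 2000.0),
)


@dataclass
class HaulRecord:
    """One midwater haul: station, immersion depth, gear geometry and catches."""

    station_id: str
    immersion_depth: float
    vertical_opening: float
    horizontal_opening: float
    distance_trawled: float | None = None
    catches: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance_trawled is None:
            # Fall back to the nominal towing protocol (speed x duration).
            self.distance_trawled = (
                TRAWL_SPEED_KN * _METERS_PER_NM * TRAWL_DURATION_H
            )
            logger.warning(
                "haul %s: distance_trawled missing, derived %.0f m from "
                "%.0f kn x %.0f h",
                self.station_id,
                self.distance_trawled,
                TRAWL_SPEED_KN,
                TRAWL_DURATION_H,
            )


def standardize_biomass(
    mass: float, vertical: float, horizontal: float, distance: float
) -> float:
    """Biomass density (kg m^-3) = catch mass / volume of water filtered."""
    if vertical <= 0 or horizontal <= 0 or distance <= 0:
        raise InvalidGearError(
            f"gear geometry must be positive, got "
            f"vertical={vertical}, horizontal={horizontal}, distance={distance}"
        )
    if mass < 0:
        raise InvalidCatchError(f"catch mass must be >= 0, got {mass}")
    return mass / (vertical * horizontal * distance)


def assign_layer(
    depth: float, layers: tuple[LayerDefinition, ...] = DEFAULT_LAYERS
) -> str:
    """Name of the unique layer containing `depth`.

    Intervals are half-open [min, max); the deepest layer additionally
    includes its upper bound, so the assignment is total on [20, 2000].
    """
    deepest = max(layers, key=lambda l: l.depth_max)
    for layer in layers:
        if layer.depth_min <= depth < layer.depth_max:
            return layer.name
        if layer is deepest and depth == layer.depth_max:
            return layer.name
    raise DepthRangeError(
        f"depth {depth} m outside sampled range "
        f"[{min(l.depth_min for l in layers)}, {deepest.depth_max}]"
    )


def build_assemblages(
    hauls: list[HaulRecord],
    level: str = "layer",
    layers: tuple[LayerDefinition, ...] = DEFAULT_LAYERS,
    layer_agg: str = "mean",
) -> pd.DataFrame:
    """Assemblage x species table of standardised biomass densities.

    level="haul" gives one row per haul (indexed by station_id);
    level="layer" aggregates haul rows within each depth layer, by default
    as the per-species mean density across the layer's hauls (robust to
    unequal haul counts; `layer_agg="sum"` totals them instead). Rows with
    an empty catch set are dropped with a warning. Row and column labels
    are sorted for stable output.
    """
    if not hauls:
        raise ValueError("need at least one haul")
    if level not in ("haul", "layer"):
        raise ValueError(f"level must be 'haul' or 'layer', got {level!r}")
    if layer_agg not in ("mean", "sum"):
        raise ValueError(f"layer_agg must be 'mean' or 'sum', got {layer_agg!r}")

    rows = {}
    haul_layer = {}
    for haul in hauls:
        if not haul.catches:
            logger.warning("haul %s: empty catch set, row dropped", haul.station_id)
            continue
        rows[haul.station_id] = {
            sp: standardize_biomass(
                mass,
                haul.vertical_opening,
                haul.horizontal_opening,
                haul.distance_trawled,
            )
            for sp, mass in haul.catches.items()
        }
        haul_layer[haul.station_id] = assign_layer(haul.immersion_depth, layers)

    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table.sort_index(axis=0).sort_index(axis=1)
    if level == "haul":
        return table
    grouped = table.groupby(pd.Series(haul_layer), sort=False)
    layer_table = grouped.mean() if layer_agg == "mean" else grouped.sum()
    order = [l.name for l in layers if l.name in layer_table.index]
    return layer_table.loc[order].sort_index(axis=1)


def read_hauls(hauls_csv, catches_csv) -> list[HaulRecord]:
    """Read haul geometry and long-format catches from two CSV files.

    hauls_csv columns: station_id, immersion_depth, vertical_opening,
    horizontal_opening, distance_trawled (optional/blank allowed).
    catches_csv columns: station_id, species, mass_kg.
    """
    hauls_df = pd.read_csv(hauls_csv)
    catches_df = pd.read_csv(catches_csv)
    catch_map: dict[str, dict[str, float]] = {}
    for rec in catches_df.itertuples(index=False):
        catch_map.setdefault(str(rec.station_id), {})[rec.species] = float(
            rec.mass_kg
        )
    hauls = []
    for rec in hauls_df.itertuples(index=False):
        distance = getattr(rec, "distance_trawled", None)
        if distance is not None and pd.isna(distance):
            distance = None
        hauls.append(
            HaulRecord(
                station_id=str(rec.station_id),
                immersion_depth=float(rec.immersion_depth),
                vertical_opening=float(rec.vertical_opening),
                horizontal_opening=float(rec.horizontal_opening),
                distance_trawled=None if distance is None else float(distance),
                catches=catch_map.get(str(rec.station_id), {}),
            )
        )
    return hauls
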