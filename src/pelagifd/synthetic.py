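"""Synthetic deep-pelagic community generator.

Emulates the statistical structure the analysis assumes, so every pipeline
stage — trait derivation, imputation, functional space, diversity indices,
null-model SES, CWM bootstrap and rarity — can be exercised end-to-end
without the deposited survey data:

* a pool of ~42 species archetypes with 26 mixed-type foraging traits whose
  distributions trend along the depth gradient (e.g. eye size shrinking,
  oral gape surface and large-teeth prevalence growing with depth);
* individuals per species (3-39, as in the reference table) whose raw
  linear measurements are back-solved from the trait formulas, so deriving
  traits from the synthetic morphometrics recovers the archetypes;
* sparse (<1%) missing measurements, missing-at-random conditioned on
  standard length (small fish lose measurements more often);
* night-trawl hauls per depth layer with log-skewed catch masses; and
* a controllable assembly mechanism per layer: neutral (uniform draws from
  the pool), filtered (species weighted towards a layer trait optimum,
  with the effective trait spread shrunk by a strength factor), or
  divergent (greedy max-min spacing in trait space).

Everything is deterministic under a master seed, fanned out to independent
per-stage streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DEFAULT_LAYERS, HaulRecord, LayerDefinition, build_assemblages
from .reference import load_species_reference
from .space import gower
from .traits import (
    BINARY_TRAITS,
    CONTINUOUS_TRAITS,
    MEASUREMENT_COLUMNS,
    ORDINAL_LEVELS,
    ORDINAL_TRAITS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySpec",
    "SpeciesPool",
    "SyntheticAssemblages",
    "generate_pool",
    "generate_individuals",
    "inject_missingness",
    "draw_assemblage",
    "generate_assemblages",
    "write_dataset",
]

_LOG_DEPTH_MIN = np.log(20.0)
_LOG_DEPTH_MAX = np.log(2000.0)

# Species archetypes follow a three-factor latent model — a depth axis
# (tied to each species' position on the log-depth gradient), a body-plan
# axis and a trophic-apparatus axis — so the 26 traits are realistically
# correlated and most trait variance concentrates on a few PCoA axes, as
# in real morphometric data. Continuous traits: trait -> (log-scale
# centre, between-species log SD, loadings on the three factors, unique
# noise SD). The two absolute traits (cm) are centred relative to
# standard length.
_CONTINUOUS_PARAMS: dict[str, tuple[float, float, tuple[float, float, float], float]] = {
    "body_depth": (np.log(0.22), 0.25, (0.0, 0.9, 0.0), 0.5),
    "caudal_throttle_width": (np.log(0.05), 0.40, (0.5, 0.7, 0.0), 0.5),
    "dorsal_fin_insertion": (np.log(0.45), 0.15, (0.0, 0.8, 0.0), 0.6),
    "eye_position": (np.log(0.45), 0.25, (0.3, 0.0, 0.6), 0.7),
    "eye_size": (np.log(0.45), 0.30, (-0.8, 0.0, 0.3), 0.5),
    "gill_outflow": (np.log(0.08), 0.30, (-0.4, 0.3, 0.6), 0.6),
    "head_length": (np.log(0.25), 0.20, (0.2, 0.4, 0.7), 0.5),
    "lower_jaw_length": (np.log(0.12), 0.35, (0.4, 0.0, 0.8), 0.5),
    "operculum_volume": (np.log(1.0), 0.30, (-0.4, 0.3, 0.6), 0.6),
    "oral_gape_position": (np.log(0.5), 0.30, (0.1, 0.0, 0.8), 0.6),
    "oral_gape_shape": (np.log(1.0), 0.30, (0.0, 0.0, 0.8), 0.6),
    "oral_gape_surface": (np.log(0.15), 0.40, (0.7, 0.0, 0.6), 0.5),
    "orbital_length": (np.log(0.06), 0.35, (-0.7, 0.0, 0.3), 0.5),
    "pectoral_fin_insertion": (np.log(0.25), 0.20, (0.0, 0.8, 0.2), 0.6),
    "pectoral_fin_position": (np.log(0.6), 0.30, (0.0, 0.8, 0.0), 0.7),
    "transversal_shape": (np.log(1.8), 0.25, (-0.4, 0.7, 0.0), 0.6),
}
_SL_RELATIVE_TRAITS = ("caudal_throttle_width", "gill_outflow")

# Binary archetypes: presence probability logistic(a0 + scale * (w . f)).
_BINARY_PARAMS: dict[str, tuple[float, tuple[float, float, float]]] = {
    "chin_barbel": (-1.5, (0.8, 0.0, 0.5)),
    "fang_teeth": (-0.5, (0.9, 0.0, 0.4)),
    "gland_head": (-1.5, (0.8, 0.0, 0.3)),
    "internal_teeth": (0.0, (0.4, 0.0, 0.6)),
    "large_teeth": (0.0, (0.9, 0.0, 0.5)),
    "ventral_photophores": (0.8, (-0.8, 0.2, 0.0)),
    "retractable_teeth": (-1.2, (0.5, 0.0, 0.5)),
    "small_teeth": (0.3, (-0.8, 0.0, -0.3)),
}
_BINARY_SCALE = 2.2


@dataclass
class CommunitySpec:
    """Tunable description of the synthetic community and survey design.

    Defaults mirror the motivating survey: 42 species, 26 traits,
    Table-2-like individual counts and depth ranges (taken from the
    packaged reference table), four depth layers with 7/27/16/18 hauls and
    richness 13/28/32/42, log-skewed biomass, <1% missing measurements,
    and a filtered epipelagic / divergent bathypelagic assembly scenario.
    """

    n_species: int = 42
    use_reference: bool = True
    layers: tuple[LayerDefinition, ...] = DEFAULT_LAYERS
    layer_richness: dict[str, int] = field(
        default_factory=lambda: {
            "epipelagic": 13,
            "upper_mesopelagic": 28,
            "lower_mesopelagic": 32,
            "bathypelagic": 42,
        }
    )
    layer_hauls: dict[str, int] = field(
        default_factory=lambda: {
            "epipelagic": 7,
            "upper_mesopelagic": 27,
            "lower_mesopelagic": 16,
            "bathypelagic": 18,
        }
    )
    assembly_modes: dict[str, str] = field(
        default_factory=lambda: {
            "epipelagic": "filtered",
            "upper_mesopelagic": "neutral",
            "lower_mesopelagic": "neutral",
            "bathypelagic": "divergent",
        }
    )
    filter_strength: float = 4.0
    missing_rate: float = 0.01
    noise_cv: float = 0.10  # intraspecific multiplicative noise (log SD)
    biomass_mu: float = np.log(0.3)  # lognormal catch mass (kg) per species
    biomass_sigma: float = 1.2
    vertical_opening: float = 24.0
    horizontal_opening: float = 58.0
    distance_trawled: float = 7408.0  # 1 h at 4 kn
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.filter_strength <= 1:
            raise ValueError("filter_strength must be > 1")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")


@dataclass
class SpeciesPool:
    """Species archetypes: true trait means and depth preferences."""

    traits: pd.DataFrame  # species x 26 true trait values
    depth_ranges: pd.DataFrame  # species x (depth_min_m, depth_max_m)
    sl_mean: pd.Series  # cm
    sl_sd: pd.Series
    n_individuals: pd.Series
    depth_position: pd.Series  # dz in [0, 1] along the log-depth gradient

    @property
    def species(self) -> pd.Index:
        return self.traits.index


def _streams(seed: int, n: int = 6) -> list[np.random.Generator]:
    """Independent per-stage generators fanned out from the master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_pool(spec: CommunitySpec) -> SpeciesPool:
    """Draw the species archetypes (true trait means, depth preferences)."""
    rng = _streams(spec.seed)[0]
    if spec.use_reference and spec.n_species == 42:
        ref = load_species_reference()
        names = ref["species"].tolist()
        depth_min = ref["depth_min_m"].to_numpy(float)
        depth_max = ref["depth_max_m"].to_numpy(float)
        sl_mean = ref["sl_mean_cm"].to_numpy(float)
        sl_sd = ref["sl_sd_cm"].to_numpy(float)
        n_ind = ref["n_individuals"].to_numpy(int)
    else:
        names = [f"sp_{i + 1:03d}" for i in range(spec.n_species)]
        centre = np.exp(rng.uniform(_LOG_DEPTH_MIN, _LOG_DEPTH_MAX, spec.n_species))
        half = rng.uniform(0.15, 0.6, spec.n_species) * (
            _LOG_DEPTH_MAX - _LOG_DEPTH_MIN
        )
        depth_min = np.maximum(20.0, np.exp(np.log(centre) - half))
        depth_max = np.minimum(2000.0, np.exp(np.log(centre) + half))
        sl_mean = np.exp(rng.normal(np.log(10.0), 0.5, spec.n_species))
        sl_sd = 0.15 * sl_mean
        n_ind = rng.integers(3, 40, spec.n_species)

    mid = np.sqrt(depth_min * depth_max)  # geometric midpoint of the range
    dz = (np.log(mid) - _LOG_DEPTH_MIN) / (_LOG_DEPTH_MAX - _LOG_DEPTH_MIN)

    # latent factors, each standardised to unit variance across the pool
    n = len(names)
    f_depth = dz + rng.normal(0, 0.12, n)
    sd = f_depth.std()
    f_depth = (f_depth - f_depth.mean()) / (sd if sd > 0 else 1.0)
    f_body = rng.normal(0, 1, n)
    f_trophic = rng.normal(0, 1, n)
    F = np.column_stack([f_depth, f_body, f_trophic])

    data: dict[str, np.ndarray] = {}
    for trait, (centre_log, sd_log, loads, uniq) in _CONTINUOUS_PARAMS.items():
        a = np.asarray(loads)
        z = F @ a + rng.normal(0, uniq, n)
        z = z / np.sqrt(a @ a + uniq**2)
        val = np.exp(centre_log + sd_log * z)
        if trait in _SL_RELATIVE_TRAITS:
            val = val * sl_mean  # absolute traits (cm) scale with body size
        data[trait] = val
    # ordinal traits from factor-linked latent scores
    g_latent = 1.0 - 1.2 * f_depth - 0.5 * f_trophic + rng.normal(0, 0.5, n)
    data["gill_raker_type"] = np.clip(np.round(g_latent), 0, 2)
    a_latent = 2.0 + 0.8 * f_depth + rng.normal(0, 0.6, n)
    data["oral_gape_axis"] = np.clip(np.round(a_latent), 0, 4)
    for trait, (a0, loads) in _BINARY_PARAMS.items():
        logit = a0 + _BINARY_SCALE * (F @ np.asarray(loads))
        p = 1.0 / (1.0 + np.exp(-logit))
        data[trait] = (rng.uniform(size=n) < p).astype(float)

    traits = pd.DataFrame(data, index=pd.Index(names, name="species"))
    traits = traits[list(CONTINUOUS_TRAITS + ORDINAL_TRAITS + BINARY_TRAITS)]
    depth_ranges = pd.DataFrame(
        {"depth_min_m": depth_min, "depth_max_m": depth_max}, index=traits.index
    )
    return SpeciesPool(
        traits=traits,
        depth_ranges=depth_ranges,
        sl_mean=pd.Series(sl_mean, index=traits.index, name="sl_mean_cm"),
        sl_sd=pd.Series(sl_sd, index=traits.index, name="sl_sd_cm"),
        n_individuals=pd.Series(n_ind, index=traits.index, name="n_individuals"),
        depth_position=pd.Series(dz, index=traits.index, name="depth_position"),
    )


def _invert_traits(traits: dict[str, float], sl: float) -> dict[str, float]:
    """Back-solve the raw linear measurements from a trait vector and SL.

    Inverts each defining ratio so that deriving traits from the emitted
    measurements reproduces the inputs exactly.
    """
    m: dict[str, float] = {"standard_length": sl}
    m["body_depth"] = traits["body_depth"] * sl
    m["body_width"] = m["body_depth"] / traits["transversal_shape"]
    m["predorsal_length"] = traits["dorsal_fin_insertion"] * sl
    m["head_length"] = traits["head_length"] * sl
    m["lower_jaw_length"] = traits["lower_jaw_length"] * sl
    m["prepectoral_length"] = traits["pectoral_fin_insertion"] * sl
    m["eye_diameter"] = traits["orbital_length"] * sl
    m["head_depth"] = m["eye_diameter"] / traits["eye_size"]
    m["eye_height"] = traits["eye_position"] * m["head_depth"]
    m["upper_jaw_bottom_head"] = traits["oral_gape_position"] * m["head_depth"]
    m["caudal_peduncle_depth"] = traits["caudal_throttle_width"]
    m["operculum_width"] = traits["gill_outflow"]
    m["operculum_depth"] = traits["operculum_volume"] * m["operculum_width"]
    m["mouth_width"] = np.sqrt(
        traits["oral_gape_surface"]
        * m["body_width"]
        * m["body_depth"]
        / traits["oral_gape_shape"]
    )
    m["mouth_depth"] = traits["oral_gape_shape"] * m["mouth_width"]
    m["body_depth_pectoral_insertion"] = 0.5 * m["body_depth"]
    m["pectoral_bottom_body"] = (
        traits["pectoral_fin_position"] * m["body_depth_pectoral_insertion"]
    )
    return m


def generate_individuals(
    pool: SpeciesPool, spec: CommunitySpec, inject_missing: bool = True
) -> pd.DataFrame:
    """Morphometric record table: one row per individual, raw measurements.

    Individual continuous trait values are the archetype times
    multiplicative lognormal noise (log SD `spec.noise_cv`); ordinal and
    binary states are fixed within species. Standard lengths are drawn
    around the species mean, capture depths uniformly within the species'
    depth range. With `inject_missing`, exactly round(rate x cells)
    observed measurement cells are removed, missing-at-random conditioned
    on standard length.
    """
    rng = _streams(spec.seed)[1]
    rows = []
    for sp in pool.species:
        arch = pool.traits.loc[sp]
        n = int(pool.n_individuals.loc[sp])
        lo, hi = pool.depth_ranges.loc[sp]
        for i in range(n):
            sl = max(
                0.3 * pool.sl_mean.loc[sp],
                rng.normal(pool.sl_mean.loc[sp], pool.sl_sd.loc[sp]),
            )
            noisy = {
                t: float(arch[t]) * np.exp(rng.normal(0, spec.noise_cv))
                for t in CONTINUOUS_TRAITS
            }
            record = _invert_traits(noisy, sl)
            record["individual_id"] = f"{sp.replace(' ', '_')}_{i + 1:02d}"
            record["species"] = sp
            record["capture_depth"] = float(rng.uniform(lo, hi))
            for t in ORDINAL_TRAITS:
                record[t] = ORDINAL_LEVELS[t][int(arch[t])]
            for t in BINARY_TRAITS:
                record[t] = float(arch[t])
            rows.append(record)
    df = pd.DataFrame(rows)
    front = ["individual_id", "species", "capture_depth"]
    df = df[front + [c for c in df.columns if c not in front]]
    if inject_missing and spec.missing_rate > 0:
        df = inject_missingness(df, spec.missing_rate, _streams(spec.seed)[2])
    return df


def inject_missingness(
    records: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Remove exactly round(rate x cells) measurement cells, MAR on size.

    Cells are drawn without replacement among the maskable measurement
    columns (everything but standard length), with row probability
    inversely proportional to standard length so small fish lose
    measurements more often.
    """
    maskable = [c for c in MEASUREMENT_COLUMNS if c != "standard_length"]
    df = records.copy()
    n_cells = int(df[maskable].notna().to_numpy().sum())
    k = int(round(rate * n_cells))
    if k == 0:
        return df
    row_w = 1.0 / df["standard_length"].to_numpy(float)
    cell_w = np.repeat(row_w, len(maskable))
    observed = df[maskable].notna().to_numpy().ravel()
    cell_w = np.where(observed, cell_w, 0.0)
    cell_w = cell_w / cell_w.sum()
    chosen = rng.choice(len(cell_w), size=k, replace=False, p=cell_w)
    arr = df[maskable].to_numpy(float)
    flat_rows, flat_cols = np.unravel_index(chosen, arr.shape)
    arr[flat_rows, flat_cols] = np.nan
    df[maskable] = arr
    return df


def draw_assemblage(
    pool: SpeciesPool,
    mode: str,
    richness: int,
    rng: np.random.Generator,
    strength: float = 4.0,
    optimum: str | None = None,
    D: pd.DataFrame | None = None,
    biomass_mu: float = np.log(0.3),
    biomass_sigma: float = 1.2,
    replace: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Select one assemblage's species and lognormal biomass weights.

    neutral: uniform sample from the pool — traits carry no information
    about membership. With `replace=True` the S trait vectors are iid
    draws with replacement, the exactly-calibrated neutral condition for
    the trait-swap null (which also resamples with replacement); the
    default keeps species distinct, as in a real assemblage.
    filtered: sample weighted by exp(-d^2 / (2 sigma^2)) where d is the
    Gower dissimilarity to the layer optimum species and sigma is the mean
    pool dissimilarity divided by `strength` — larger strength shrinks the
    realised trait spread. divergent: greedy max-min spacing, seeded by
    the most distant pair.
    """
    if richness > len(pool.species) and not (mode == "neutral" and replace):
        raise ValueError(
            f"requested richness {richness} exceeds pool size {len(pool.species)}"
        )
    if mode not in ("neutral", "filtered", "divergent"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    species = list(pool.species)
    if mode == "neutral":
        idx = rng.choice(len(species), size=richness, replace=replace)
        chosen = [species[i] for i in idx]
    else:
        if D is None:
            D = gower(pool.traits)
        A = D.to_numpy()
        if mode == "filtered":
            if optimum is None:
                opt_idx = int(rng.integers(0, len(species)))
            else:
                opt_idx = species.index(optimum)
            d = A[opt_idx]
            sigma = A[np.triu_indices(len(A), k=1)].mean() / strength
            logw = -0.5 * (d / sigma) ** 2
            # Gumbel top-k = weighted sampling without replacement
            keys = logw + rng.gumbel(size=len(species))
            chosen = [species[i] for i in np.argsort(keys)[::-1][:richness]]
        else:  # divergent
            i0, j0 = np.unravel_index(np.argmax(A), A.shape)
            selected = [int(i0), int(j0)]
            while len(selected) < richness:
                rest = [i for i in range(len(species)) if i not in selected]
                min_d = A[np.ix_(rest, selected)].min(axis=1)
                selected.append(rest[int(np.argmax(min_d))])
            chosen = [species[i] for i in selected[:richness]]
    masses = np.exp(rng.normal(biomass_mu, biomass_sigma, size=len(chosen)))
    weights = masses / masses.sum()
    return chosen, weights


@dataclass
class SyntheticAssemblages:
    """Hauls, layer assemblage table, occurrence depths and ground truth."""

    hauls: list[HaulRecord]
    layer_table: pd.DataFrame  # layer x species standardized densities
    layer_species: dict[str, list[str]]
    layer_weights: dict[str, np.ndarray]
    occurrence_depths: dict[str, tuple[float, float]]
    modes: dict[str, str]


def generate_assemblages(pool: SpeciesPool, spec: CommunitySpec) -> SyntheticAssemblages:
    """Draw layer assemblages and the trawl hauls realising them.

    Per layer: species are selected by the configured assembly mode with
    the configured richness, then the layer's hauls (uniform immersion
    depths within the layer) catch a random subset of the layer species
    with log-skewed masses; every selected species is forced into at least
    one haul so the layer assemblage realises the drawn composition.
    """
    rng = _streams(spec.seed)[3]
    D = gower(pool.traits)
    hauls: list[HaulRecord] = []
    layer_species: dict[str, list[str]] = {}
    layer_weights: dict[str, np.ndarray] = {}
    occ: dict[str, list[float]] = {}
    for layer in spec.layers:
        mode = spec.assembly_modes.get(layer.name, "neutral")
        richness = spec.layer_richness.get(layer.name, len(pool.species))
        if mode == "filtered":
            # deterministic layer optimum: species whose depth-range
            # midpoint is nearest the layer midpoint
            mid = 0.5 * (layer.depth_min + layer.depth_max)
            centres = pool.depth_ranges.mean(axis=1)
            optimum = (centres - mid).abs().idxmin()
        else:
            optimum = None
        chosen, weights = draw_assemblage(
            pool,
            mode,
            richness,
            rng,
            strength=spec.filter_strength,
            optimum=optimum,
            D=D,
            biomass_mu=spec.biomass_mu,
            biomass_sigma=spec.biomass_sigma,
        )
        layer_species[layer.name] = chosen
        layer_weights[layer.name] = weights
        n_hauls = spec.layer_hauls.get(layer.name, 5)
        total_mass = weights * np.exp(
            rng.normal(spec.biomass_mu, 0.5)
        ) * len(chosen)
        haul_catches: list[dict[str, float]] = [{} for _ in range(n_hauls)]
        for s_idx, sp in enumerate(chosen):
            present = rng.uniform(size=n_hauls) < 0.6
            if not present.any():
                present[rng.integers(0, n_hauls)] = True
            shares = rng.dirichlet(np.ones(int(present.sum())))
            for share, h_idx in zip(shares, np.where(present)[0]):
                haul_catches[h_idx][sp] = float(total_mass[s_idx] * share)
        for h_idx in range(n_hauls):
            depth = float(rng.uniform(layer.depth_min, layer.depth_max))
            station = f"{layer.name}_{h_idx + 1:02d}"
            hauls.append(
                HaulRecord(
                    station_id=station,
                    immersion_depth=depth,
                    vertical_opening=spec.vertical_opening,
                    horizontal_opening=spec.horizontal_opening,
                    distance_trawled=spec.distance_trawled,
                    catches=haul_catches[h_idx],
                )
            )
            for sp in haul_catches[h_idx]:
                occ.setdefault(sp, []).append(depth)
    layer_table = build_assemblages(hauls, level="layer", layers=spec.layers)
    occurrence = {sp: (min(ds), max(ds)) for sp, ds in occ.items()}
    return SyntheticAssemblages(
        hauls=hauls,
        layer_table=layer_table,
        layer_species=layer_species,
        layer_weights=layer_weights,
        occurrence_depths=occurrence,
        modes=dict(spec.assembly_modes),
    )


def write_dataset(spec: CommunitySpec, outdir: str | Path) -> dict[str, Path]:
    """Emit the CSV dialects the ingest and traits modules read.

    Writes morphometrics.csv (raw individual measurements), hauls.csv and
    catches.csv (long format), and ground_truth.json (archetypes, assembly
    modes, seeds) for recovery tests. Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool = generate_pool(spec)
    individuals = generate_individuals(pool, spec)
    assemblages = generate_assemblages(pool, spec)

    paths = {
        "morphometrics": outdir / "morphometrics.csv",
        "hauls": outdir / "hauls.csv",
        "catches": outdir / "catches.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    individuals.to_csv(paths["morphometrics"], index=False)
    pd.DataFrame(
        [
            {
                "station_id": h.station_id,
                "immersion_depth": h.immersion_depth,
                "vertical_opening": h.vertical_opening,
                "horizontal_opening": h.horizontal_opening,
                "distance_trawled": h.distance_trawled,
            }
            for h in assemblages.hauls
        ]
    ).to_csv(paths["hauls"], index=False)
    pd.DataFrame(
        [
            {"station_id": h.station_id, "species": sp, "mass_kg": mass}
            for h in assemblages.hauls
            for sp, mass in h.catches.items()
        ]
    ).to_csv(paths["catches"], index=False)
    truth = {
        "seed": spec.seed,
        "n_species": spec.n_species,
        "assembly_modes": assemblages.modes,
        "archetype_traits": {
            sp: {t: float(v) for t, v in row.items()}
            for sp, row in pool.traits.iterrows()
        },
        "depth_ranges": {
            sp: [float(row["depth_min_m"]), float(row["depth_max_m"])]
            for sp, row in pool.depth_ranges.iterrows()
        },
        "layer_species": assemblages.layer_species,
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    return paths
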