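"""Orchestration: ingest -> traits -> space -> indices -> SES -> CWM -> rarity.

:func:`run_pipeline` executes the whole analysis from a single
:class:`RunConfig`, writes every intermediate artifact as labelled CSV (or
JSON) into the output directory, and returns a machine-readable run report.
A single master seed fans out to independent per-stage streams via
``numpy.random.SeedSequence.spawn`` (fixed stage order: imputation, null
model, CWM bootstrap), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cwm import CWM_TRAITS, cwm_bootstrap, cwm_pca, cwm_point
from .diversity import compute_indices
from .ingest import DEFAULT_LAYERS, assign_layer, build_assemblages, read_hauls
from .nullmodel import null_model_ses, ses_table
from .rarity import rarity_table
from .space import gower, hull_vertices, pcoa, quality_profile
from .synthetic import CommunitySpec, write_dataset
from .traits import (
    derive_trait_table,
    exclude_sparse_species,
    impute_missing,
    summarise_species,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a full run needs; serialised into the output directory."""

    outdir: str = "results/run"
    # inputs: either the three CSVs, or synthetic generation
    morphometrics_csv: str | None = None
    hauls_csv: str | None = None
    catches_csv: str | None = None
    synthetic: bool = True
    synthetic_spec: dict = field(default_factory=dict)
    # analysis settings
    m: int = 4
    correction: str = "sqrt"
    exclusion_threshold: float = 0.25
    imputation_m: int = 5
    imputation_iterations: int = 50
    n_sim: int = 999
    alpha: float = 0.05
    z_threshold: float = 1.96
    n_boot: int = 999
    sample_size: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_sim < 2 or self.n_boot < 2:
            raise ValueError("n_sim and n_boot must be >= 2")
        if not self.synthetic and not (
            self.morphometrics_csv and self.hauls_csv and self.catches_csv
        ):
            raise ValueError("non-synthetic runs need the three input CSVs")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("imputation", "null_model", "cwm_bootstrap")
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write all artifacts under `outdir`."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "warnings": [],
        "timings_s": {},
        "artifacts": [],
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    def _tick(stage: str, t0: float) -> None:
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    # -- ingest ------------------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic:
        spec = CommunitySpec(seed=config.seed, **config.synthetic_spec)
        data_paths = write_dataset(spec, outdir / "data")
        config.morphometrics_csv = str(data_paths["morphometrics"])
        config.hauls_csv = str(data_paths["hauls"])
        config.catches_csv = str(data_paths["catches"])
    hauls = read_hauls(config.hauls_csv, config.catches_csv)
    layer_table = build_assemblages(hauls, level="layer")
    haul_table = build_assemblages(hauls, level="haul")
    haul_depths = {h.station_id: h.immersion_depth for h in hauls}
    occurrence: dict[str, tuple[float, float]] = {}
    for h in hauls:
        for sp in h.catches:
            lo, hi = occurrence.get(sp, (h.immersion_depth, h.immersion_depth))
            occurrence[sp] = (
                min(lo, h.immersion_depth),
                max(hi, h.immersion_depth),
            )
    layer_table.to_csv(outdir / "assemblage_layers.csv")
    haul_table.to_csv(outdir / "assemblage_hauls.csv")
    _tick("ingest", t0)

    # -- traits ------------------------------------------------------------
    t0 = time.perf_counter()
    records = pd.read_csv(config.morphometrics_csv)
    individual_traits = derive_trait_table(records)
    individual_traits, excluded = exclude_sparse_species(
        individual_traits, threshold=config.exclusion_threshold
    )
    if excluded:
        report["warnings"].append(f"species excluded as too sparse: {excluded}")
    completed = impute_missing(
        individual_traits,
        m=config.imputation_m,
        iterations=config.imputation_iterations,
        seed=seeds["imputation"],
    )
    matrix, meta = summarise_species(completed)
    matrix.to_csv(outdir / "species_traits.csv")
    meta.to_csv(outdir / "species_metadata.csv")
    _tick("traits", t0)

    # keep only species both measured and caught
    caught = set(layer_table.columns)
    community = [sp for sp in matrix.index if sp in caught]
    dropped = sorted(caught - set(matrix.index))
    if dropped:
        report["warnings"].append(f"caught but unmeasured species dropped: {dropped}")
    matrix = matrix.loc[community]

    # -- functional space --------------------------------------------------
    t0 = time.perf_counter()
    D = gower(matrix)
    D.to_csv(outdir / "gower.csv")
    space = pcoa(D, correction=config.correction)
    space.m = config.m
    profile = quality_profile(D, space)
    space.coordinates.to_csv(outdir / "pcoa_coordinates.csv")
    pd.DataFrame(
        {"m": list(profile.keys()), "mSD": list(profile.values())}
    ).to_csv(outdir / "space_quality.csv", index=False)
    hull = hull_vertices(space)
    (outdir / "hull.json").write_text(
        json.dumps(
            {
                "m": hull.m,
                "volume": hull.volume,
                "vertices": hull.vertices,
                "non_vertices": hull.non_vertices,
                "pcoa_pct_variation": [
                    round(100 * p, 4) for p in space.proportion_explained
                ],
            },
            indent=1,
        )
    )
    _tick("space", t0)

    # -- diversity indices + null-model SES per layer ----------------------
    t0 = time.perf_counter()
    null_rng_seeds = np.random.SeedSequence(seeds["null_model"]).spawn(
        len(layer_table.index)
    )
    index_rows = []
    ses_results = {}
    for layer_name, child in zip(layer_table.index, null_rng_seeds):
        row = layer_table.loc[layer_name]
        present = [sp for sp in community if row.get(sp, 0) > 0]
        weights = row[present].to_numpy(float)
        weights = weights / weights.sum()
        if len(present) < 3:
            report["warnings"].append(
                f"layer {layer_name}: fewer than 3 species, indices skipped"
            )
            continue
        idx = compute_indices(
            space, present, weights, community_volume=hull.volume
        )
        index_rows.append(
            {
                "assemblage": layer_name,
                "fric": idx.fric,
                "fric_fraction": idx.fric_fraction,
                "feve": idx.feve,
                "fdis": idx.fdis,
                "fdiv": idx.fdiv,
                "m_used": idx.m_used,
                "flags": "; ".join(idx.flags),
            }
        )
        ses_results[layer_name] = null_model_ses(
            space,
            present,
            weights,
            n_sim=config.n_sim,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            alpha=config.alpha,
            z_threshold=config.z_threshold,
        )
    pd.DataFrame(index_rows).to_csv(outdir / "diversity_indices.csv", index=False)
    ses_df = ses_table(ses_results)
    ses_df.to_csv(outdir / "ses.csv", index=False)
    _tick("diversity_ses", t0)

    # -- CWM bootstrap per sampling depth + PCA of layer medians -----------
    t0 = time.perf_counter()
    boot_rng = np.random.SeedSequence(seeds["cwm_bootstrap"])
    cwm_traits = [t for t in CWM_TRAITS if t in completed.columns]
    cwm_rows = []
    stations = list(haul_table.index)
    child_seeds = boot_rng.spawn(len(stations))
    for station, child in zip(stations, child_seeds):
        depth = haul_depths[station]
        biomass = haul_table.loc[station]
        biomass = biomass[biomass > 0]
        biomass = biomass[[sp for sp in biomass.index if sp in set(community)]]
        if biomass.empty:
            continue
        layer_name = assign_layer(depth)
        sub_seeds = np.random.SeedSequence(
            int(child.generate_state(1)[0] % (2**31 - 1))
        ).spawn(len(cwm_traits))
        for trait, tseed in zip(cwm_traits, sub_seeds):
            dist = cwm_bootstrap(
                completed,
                biomass,
                trait,
                depth=depth,
                n_boot=config.n_boot,
                sample_size=config.sample_size,
                seed=int(tseed.generate_state(1)[0] % (2**31 - 1)),
            )
            point = cwm_point(matrix[trait], biomass)
            cwm_rows.append(
                {
                    "trait": trait,
                    "station": station,
                    "depth": depth,
                    "layer": layer_name,
                    "boot_mean": dist.mean,
                    "ci_low": dist.ci_low,
                    "ci_high": dist.ci_high,
                    "point_cwm": point,
                }
            )
    cwm_df = pd.DataFrame(cwm_rows)
    cwm_df.to_csv(outdir / "cwm.csv", index=False)
    medians = cwm_df.pivot_table(
        index="layer", columns="trait", values="boot_mean", aggfunc="median"
    )
    layer_order = [l.name for l in DEFAULT_LAYERS if l.name in medians.index]
    medians = medians.loc[layer_order]
    loadings, scores, pct = cwm_pca(medians)
    loadings.to_csv(outdir / "cwm_pca_loadings.csv")
    scores.to_csv(outdir / "cwm_pca_scores.csv")
    pd.DataFrame({"component": loadings.columns, "pct_variance": pct}).to_csv(
        outdir / "cwm_pca_variance.csv", index=False
    )
    _tick("cwm", t0)

    # -- functional rarity -------------------------------------------------
    t0 = time.perf_counter()
    all_depths = [h.immersion_depth for h in hauls]
    rarity = rarity_table(
        D,
        {sp: occurrence[sp] for sp in community if sp in occurrence},
        depth_min=min(all_depths),
        depth_max=max(all_depths),
    )
    rarity.to_csv(outdir / "rarity.csv")
    _tick("rarity", t0)

    report["artifacts"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
    )
    report["n_species"] = len(community)
    report["excluded_species"] = excluded
    report["pcoa_pct_variation_first_axes"] = [
        round(100 * p, 4) for p in space.proportion_explained[: config.m]
    ]
    report["hull_vertex_count"] = len(hull.vertices)
    report["cwm_pca_pct_variance"] = [round(float(v), 4) for v in pct]
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
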