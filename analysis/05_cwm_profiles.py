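"""Bootstrapped community-weighted means and the PCA of layer profiles.

For every trait (except the two nominal-use ordinal ones) and every
sampling depth, bootstraps the biomass-weighted mean over individual
trait values (999 draws x 200 individuals, selection proportional to
species biomass). The PCA of the layer-median CWM profiles summarises how
the biomass-dominant foraging strategy shifts with depth.
"""

import numpy as np
import pandas as pd

from pelagifd.cwm import CWM_TRAITS, cwm_bootstrap, cwm_pca
from pelagifd.ingest import assign_layer, build_assemblages, read_hauls

SEED = 1
N_BOOT = 999
SAMPLE_SIZE = 200

if __name__ == "__main__":
    completed = pd.read_csv("results/individual_traits.csv")
    hauls = read_hauls("results/data/hauls.csv", "results/data/catches.csv")
    haul_table = build_assemblages(hauls, level="haul")
    depths = {h.station_id: h.immersion_depth for h in hauls}

    rng = np.random.default_rng(SEED)
    rows = []
    for station in haul_table.index:
        biomass = haul_table.loc[station]
        biomass = biomass[biomass > 0]
        for trait in CWM_TRAITS:
            dist = cwm_bootstrap(
                completed, biomass, trait, depth=depths[station],
                n_boot=N_BOOT, sample_size=SAMPLE_SIZE,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {"trait": trait, "station": station, "depth": depths[station],
                 "layer": assign_layer(depths[station]),
                 "boot_mean": dist.mean, "ci_low": dist.ci_low,
                 "ci_high": dist.ci_high}
            )
    cwm = pd.DataFrame(rows)
    cwm.to_csv("results/cwm.csv", index=False)

    medians = cwm.pivot_table(
        index="layer", columns="trait", values="boot_mean", aggfunc="median"
    ).loc[["epipelagic", "upper_mesopelagic", "lower_mesopelagic", "bathypelagic"]]
    loadings, scores, pct = cwm_pca(medians)
    loadings.to_csv("results/cwm_pca_loadings.csv")
    scores.to_csv("results/cwm_pca_scores.csv")

    print(f"CWM bootstrap: {cwm['station'].nunique()} depths x "
          f"{cwm['trait'].nunique()} traits")
    print(f"layer-profile PCA: PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}% of variance")
    lead = loadings["pc_1"].abs().sort_values(ascending=False).head(5)
    print("traits driving PC1:", ", ".join(lead.index))
    deep_vs_shallow = (
        medians.loc["bathypelagic"] - medians.loc["epipelagic"]
    ).sort_values()
    print("largest epipelagic-vs-bathypelagic CWM shifts:",
          ", ".join(deep_vs_shallow.abs().sort_values(ascending=False).head(4).index))
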