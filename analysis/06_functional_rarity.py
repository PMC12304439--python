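"""Functional rarity: trait uniqueness vs depth-range restrictedness.

Uniqueness is each species' smallest Gower dissimilarity to any other
community member; restrictedness is one minus the occupied fraction of
the sampled 20-2000 m depth extent (occurrences taken from the haul
catches). Species above both community medians are the functionally
rarest — typically low-biomass specialists confined to the deep layers.
"""

import pandas as pd

from pelagifd.ingest import read_hauls
from pelagifd.rarity import rarity_table

if __name__ == "__main__":
    D = pd.read_csv("results/gower.csv", index_col=0)
    hauls = read_hauls("results/data/hauls.csv", "results/data/catches.csv")
    occurrence = {}
    for h in hauls:
        for sp in h.catches:
            lo, hi = occurrence.get(sp, (h.immersion_depth, h.immersion_depth))
            occurrence[sp] = (min(lo, h.immersion_depth), max(hi, h.immersion_depth))
    depths = [h.immersion_depth for h in hauls]
    table = rarity_table(
        D, {sp: occurrence[sp] for sp in D.index if sp in occurrence},
        depth_min=min(depths), depth_max=max(depths),
    )
    table.to_csv("results/rarity.csv")

    rare = table[table["unique_above_median"] & table["restricted_above_median"]]
    common = table[~table["unique_above_median"] & ~table["restricted_above_median"]]
    print(f"{len(table)} species scored; "
          f"{len(rare)} functionally rare (both indices above median)")
    print("rarest (uniqueness x restrictedness):")
    ranked = (table["uniqueness"] * table["restrictedness"]).sort_values()
    for sp in ranked.index[-5:][::-1]:
        print(f"  {sp}: U={table.loc[sp,'uniqueness']:.3f} "
              f"R={table.loc[sp,'restrictedness']:.3f}")
    print("most common:", ", ".join(ranked.index[:3]))
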