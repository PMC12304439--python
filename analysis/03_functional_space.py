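"""Build the functional space: Gower dissimilarity, PCoA, quality, hull.

The mixed-type species x trait matrix becomes a Gower dissimilarity
matrix, embedded by PCoA (square-root correction for negative
eigenvalues). The quality profile (mean squared deviation between
embedded and trait-based distances) supports the 4-axis compromise; the
convex hull of the community identifies the vertex species carrying the
most extreme trait combinations.
"""

import json

import pandas as pd

from pelagifd.space import gower, hull_vertices, pcoa, quality_profile

M_AXES = 4

if __name__ == "__main__":
    matrix = pd.read_csv("results/species_traits.csv", index_col=0)
    D = gower(matrix)
    space = pcoa(D, correction="sqrt")
    space.m = M_AXES
    profile = quality_profile(D, space)
    hull = hull_vertices(space)

    D.to_csv("results/gower.csv")
    space.coordinates.to_csv("results/pcoa_coordinates.csv")
    pd.DataFrame({"m": profile.keys(), "mSD": profile.values()}).to_csv(
        "results/space_quality.csv", index=False
    )
    with open("results/hull.json", "w") as fh:
        json.dump(
            {"m": hull.m, "volume": hull.volume, "vertices": hull.vertices},
            fh, indent=1,
        )

    pct = 100 * space.proportion_explained
    print(f"PCoA variance: axis1 {pct[0]:.1f}%, axis2 {pct[1]:.1f}%, "
          f"first {M_AXES} axes {pct[:M_AXES].sum():.1f}%")
    print(f"quality profile (mSD): " +
          ", ".join(f"m={m}: {v:.4f}" for m, v in profile.items()))
    print(f"{len(hull.vertices)} vertex species of {len(matrix)}; "
          f"hull volume {hull.volume:.4g}")
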