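"""Reference community table for the Bay of Biscay deep-pelagic fish assemblage.

The packaged table lists the 42 epi- to bathypelagic species sampled by
night-time midwater trawling between 20 and 2000 m, with each species'
observed depth range (m), the number of measured individuals, and the mean
and standard deviation of standard length (cm). It seeds the synthetic
community generator with realistic sample sizes, body sizes and
depth-occupancy structure, and feeds the depth-range restrictedness index.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_species_reference"]


def load_species_reference() -> pd.DataFrame:
    """Return the 42-species reference table as a DataFrame.

    Columns: order, family, species, depth_min_m, depth_max_m,
    n_individuals, sl_mean_cm, sl_sd_cm.
    """
    ref = resources.files("pelagifd.data").joinpath("bay_of_biscay_species.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df
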