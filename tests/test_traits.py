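import numpy as np
import pandas as pd
import pytest

from pelagifd.errors import CannotImputeError, ConfigError
from pelagifd.traits import (
    BINARY_TRAITS,
    CONTINUOUS_TRAITS,
    MEASUREMENT_COLUMNS,
    TRAIT_NAMES,
    derive_traits,
    derive_trait_table,
    exclude_sparse_species,
    impute_missing,
    summarise_species,
)


def full_record(**overrides):
    rec = {
        "standard_length": 10.0,
        "body_depth": 2.0,
        "body_width": 1.0,
        "head_length": 2.5,
        "head_depth": 1.8,
        "eye_diameter": 0.6,
        "eye_height": 0.9,
        "lower_jaw_length": 1.2,
        "mouth_width": 0.8,
        "mouth_depth": 0.9,
        "operculum_width": 0.7,
        "operculum_depth": 0.8,
        "predorsal_length": 4.5,
        "prepectoral_length": 2.8,
        "caudal_peduncle_depth": 0.4,
        "upper_jaw_bottom_head": 1.0,
        "pectoral_bottom_body": 0.7,
        "body_depth_pectoral_insertion": 1.1,
        "gill_raker_type": "low_developed",
        "oral_gape_axis": "terminal",
        **{t: 0.0 for t in BINARY_TRAITS},
    }
    rec.update(overrides)
    return rec


class TestDeriveTraits:
    def test_eye_size_is_one_when_eye_equals_head_depth(self):
        t = derive_traits(full_record(eye_diameter=1.8, head_depth=1.8))
        assert t["eye_size"] == pytest.approx(1.0)

    def test_oral_gape_surface_hand_value(self):
        # 1x1 cm mouth on a 2x2 cm body cross-section
        t = derive_traits(
            full_record(mouth_width=1.0, mouth_depth=1.0, body_width=2.0, body_depth=2.0)
        )
        assert t["oral_gape_surface"] == pytest.approx(0.25)

    def test_all_formula_values_on_one_record(self):
        rec = full_record()
        t = derive_traits(rec)
        assert t["body_depth"] == pytest.approx(0.2)
        assert t["transversal_shape"] == pytest.approx(2.0)
        assert t["caudal_throttle_width"] == pytest.approx(0.4)  # absolute
        assert t["gill_outflow"] == pytest.approx(0.7)  # absolute
        assert t["operculum_volume"] == pytest.approx(0.8 / 0.7)
        assert t["pectoral_fin_position"] == pytest.approx(0.7 / 1.1)
        assert t["oral_gape_axis"] == 2.0  # rank of "terminal"

    def test_missing_inputs_propagate_binaries_pass_through(self):
        rec = {
            "standard_length": 10.0,
            "gill_raker_type": np.nan,
            "oral_gape_axis": np.nan,
            **{t: 1.0 for t in BINARY_TRAITS},
        }
        t = derive_traits(rec)
        for trait in CONTINUOUS_TRAITS:
            assert np.isnan(t[trait])
        assert all(t[b] == 1.0 for b in BINARY_TRAITS)

    def test_scale_awareness(self):
        # doubling every linear measurement leaves ratios unchanged and
        # doubles the two absolute traits
        rec = full_record()
        doubled = {
            k: (2 * v if k in MEASUREMENT_COLUMNS else v) for k, v in rec.items()
        }
        t1, t2 = derive_traits(rec), derive_traits(doubled)
        for trait in CONTINUOUS_TRAITS:
            if trait in ("caudal_throttle_width", "gill_outflow"):
                assert t2[trait] == pytest.approx(2 * t1[trait])
            else:
                assert t2[trait] == pytest.approx(t1[trait])

    def test_zero_denominator_emits_missing(self):
        t = derive_traits(full_record(head_depth=0.0))
        assert np.isnan(t["eye_size"])

    def test_standard_length_required(self):
        with pytest.raises(ValueError):
            derive_traits({"body_depth": 1.0})


def _trait_table(missing_by_species: dict[str, int]) -> pd.DataFrame:
    """One individual per species; the first k traits fully missing."""
    rows = []
    for sp, k in missing_by_species.items():
        row = {"species": sp, "individual_id": f"{sp}_1"}
        for i, trait in enumerate(TRAIT_NAMES):
            row[trait] = np.nan if i < k else 1.0
        rows.append(row)
    return pd.DataFrame(rows)


class TestExcludeSparseSpecies:
    def test_boundary_seven_vs_six_missing_traits(self):
        table = _trait_table({"gulper": 7, "lanternfish": 6, "hatchetfish": 0})
        kept, excluded = exclude_sparse_species(table, threshold=0.25)
        # 7/26 = 26.9% > 25% excluded; 6/26 = 23.1% retained
        assert excluded == ["gulper"]
        assert set(kept["species"]) == {"lanternfish", "hatchetfish"}

    def test_complete_table_identity(self):
        table = _trait_table({"a": 0, "b": 0})
        kept, excluded = exclude_sparse_species(table)
        assert excluded == []
        pd.testing.assert_frame_equal(kept, table)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 2])
    def test_threshold_validation(self, threshold):
        with pytest.raises(ConfigError):
            exclude_sparse_species(_trait_table({"a": 0}), threshold=threshold)


class TestImputation:
    def test_complete_table_returned_unchanged(self):
        table = _trait_table({"a": 0, "b": 0, "c": 0})
        out = impute_missing(table, seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(5)
        n = 60
        base = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(n, len(TRAIT_NAMES))), columns=TRAIT_NAMES
        )
        for b in BINARY_TRAITS:
            base[b] = rng.integers(0, 2, n).astype(float)
        base["gill_raker_type"] = rng.integers(0, 3, n).astype(float)
        base["oral_gape_axis"] = rng.integers(0, 5, n).astype(float)
        base["species"] = "x"
        holed = base.copy()
        holed.loc[3, "eye_size"] = np.nan
        holed.loc[10, "large_teeth"] = np.nan
        out = impute_missing(holed, seed=1, iterations=5)
        mask = holed[list(TRAIT_NAMES)].notna()
        pd.testing.assert_frame_equal(
            out[list(TRAIT_NAMES)].where(mask), holed[list(TRAIT_NAMES)].where(mask)
        )
        assert not out[list(TRAIT_NAMES)].isna().any().any()

    def test_perfect_predictor_single_donor_recovers_value(self):
        # y = 2x exactly; the missing row shares its predictor value with
        # one observed row, so with a donor pool of one PMM must copy that
        # donor's observed value (prediction distance exactly zero)
        x = np.append(np.arange(1.0, 21.0), 8.0)
        table = pd.DataFrame(
            {
                "eye_size": x,
                "body_depth": 2 * x,
                "head_length": np.ones(len(x)),
                "species": "x",
            }
        )
        table.loc[20, "body_depth"] = np.nan  # true value 2*8=16
        out = impute_missing(table, m=1, iterations=10, seed=0, k=1)
        assert out.loc[20, "body_depth"] == pytest.approx(16.0)

    def test_mar_imputation_beats_mean_imputation(self):
        # correlated traits, 1% MAR holes: PMM RMSE < marginal-SD baseline
        rng = np.random.default_rng(12)
        n = 300
        latent = rng.normal(size=n)
        cols = {}
        for i, trait in enumerate(CONTINUOUS_TRAITS[:8]):
            cols[trait] = np.exp(0.8 * latent + 0.2 * rng.normal(size=n))
        truth = pd.DataFrame(cols)
        holed = truth.copy()
        cells = [(r, c) for r in range(n) for c in range(8)]
        pick = rng.choice(len(cells), size=int(0.01 * n * 8), replace=False)
        for p in pick:
            r, c = cells[p]
            holed.iloc[r, c] = np.nan
        holed["species"] = "x"
        out = impute_missing(holed, m=5, iterations=10, seed=3)
        errs, base_errs = [], []
        col_means = holed[truth.columns].mean()
        for p in pick:
            r, c = cells[p]
            trait = truth.columns[c]
            errs.append(out.iloc[r][trait] - truth.iloc[r, c])
            base_errs.append(col_means[trait] - truth.iloc[r, c])
        rmse = np.sqrt(np.mean(np.square(errs)))
        rmse_mean = np.sqrt(np.mean(np.square(base_errs)))
        assert rmse < rmse_mean

    def test_all_missing_column_rejected(self):
        table = _trait_table({"a": 1, "b": 1, "c": 1})
        with pytest.raises(CannotImputeError):
            impute_missing(table, seed=0)


class TestSummariseSpecies:
    def test_single_individual_is_its_own_summary(self):
        rec = pd.DataFrame([full_record() | {"species": "solo", "individual_id": "s1"}])
        table = derive_trait_table(rec)
        matrix, meta = summarise_species(table)
        derived = derive_traits(full_record())
        for trait in TRAIT_NAMES:
            assert matrix.loc["solo", trait] == pytest.approx(derived[trait])
        assert meta.loc["solo", "n_individuals"] == 1

    def test_mean_median_majority_aggregation(self):
        rows = []
        for i, (es, grt, lt) in enumerate(
            [(0.4, 0, 1.0), (0.6, 1, 1.0), (0.8, 1, 0.0)]
        ):
            row = {t: 1.0 for t in TRAIT_NAMES}
            row.update(
                {
                    "species": "m",
                    "individual_id": f"m{i}",
                    "eye_size": es,
                    "gill_raker_type": grt,
                    "large_teeth": lt,
                }
            )
            rows.append(row)
        matrix, _ = summarise_species(pd.DataFrame(rows))
        assert matrix.loc["m", "eye_size"] == pytest.approx(0.6)  # mean
        assert matrix.loc["m", "gill_raker_type"] == 1.0  # median category
        assert matrix.loc["m", "large_teeth"] == 1.0  # 2/3 majority

    def test_incomplete_table_rejected(self):
        table = _trait_table({"a": 2})
        with pytest.raises(ValueError):
            summarise_species(table)
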