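import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from helpers import gower_bruteforce, is_hull_vertex_lp
from pelagifd.errors import ConfigError, DegenerateSpaceError, DimensionalityError
from pelagifd.space import (
    FunctionalSpace,
    gower,
    hull_vertices,
    pcoa,
    quality_profile,
    space_quality,
)
from pelagifd.traits import BINARY_TRAITS, TRAIT_NAMES


class TestGower:
    def test_identical_rows_have_zero_dissimilarity(self, mixed_matrix):
        df, kinds = mixed_matrix
        df2 = pd.concat([df, df.iloc[[0]].rename(index={"sp0": "clone"})])
        D = gower(df2, kinds)
        assert D.loc["sp0", "clone"] == 0.0

    def test_eight_binary_differences_over_26_traits(self):
        # two species identical on 18 traits, opposite on all 8 binaries
        base = {t: 1.0 for t in TRAIT_NAMES}
        a = dict(base, **{b: 0.0 for b in BINARY_TRAITS})
        b = dict(base, **{b: 1.0 for b in BINARY_TRAITS})
        # a third species gives the continuous columns nonzero range so
        # every trait keeps unit weight
        c = {t: (2.0 if t not in BINARY_TRAITS else 0.0) for t in TRAIT_NAMES}
        df = pd.DataFrame([a, b, c], index=["a", "b", "c"])
        D = gower(df)
        assert D.loc["a", "b"] == pytest.approx(8 / 26, abs=1e-12)

    def test_matches_bruteforce_on_grid(self):
        df = pd.DataFrame(
            {"c1": [0.0, 1.0, 2.0], "c2": [0.0, 2.0, 4.0]},
            index=["a", "b", "c"],
        )
        kinds = {"c1": "continuous", "c2": "continuous"}
        D = gower(df, kinds)
        expected = gower_bruteforce(df, kinds)
        np.testing.assert_allclose(D.to_numpy(), expected, atol=1e-12)

    def test_matches_bruteforce_on_mixed_matrix(self, mixed_matrix):
        df, kinds = mixed_matrix
        np.testing.assert_allclose(
            gower(df, kinds).to_numpy(), gower_bruteforce(df, kinds), atol=1e-12
        )

    def test_symmetric_zero_diagonal_bounded(self, gower42):
        A = gower42.to_numpy()
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 0)
        assert A.min() >= 0 and A.max() <= 1

    def test_invariant_to_column_order(self, mixed_matrix):
        df, kinds = mixed_matrix
        shuffled = df[list(df.columns[::-1])]
        pd.testing.assert_frame_equal(gower(df, kinds), gower(shuffled, kinds))

    def test_invariant_to_monotone_ordinal_relabelling(self, mixed_matrix):
        df, kinds = mixed_matrix
        relabelled = df.copy()
        relabelled["o1"] = df["o1"].map({0: 10.0, 1: 55.0, 2: 70.0})
        pd.testing.assert_frame_equal(gower(df, kinds), gower(relabelled, kinds))

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame({"c1": [1.0, 1.0], "b1": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(DegenerateSpaceError):
            gower(df, {"c1": "continuous", "b1": "binary"})


def _euclidean_D(pts, labels=None):
    labels = labels or [f"p{i}" for i in range(len(pts))]
    return pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)


class TestPcoa:
    def test_planar_points_embedded_exactly(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [0.0, 1.5]])
        space = pcoa(_euclidean_D(pts))
        embedded = space.axes(2)
        np.testing.assert_allclose(
            pdist(embedded), pdist(pts), atol=1e-8
        )
        assert space.correction == "none"

    def test_three_equidistant_species(self):
        D = _euclidean_D(np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]))
        space = pcoa(D)
        lam = space.eigenvalues
        assert len(lam) == 2
        assert lam[0] == pytest.approx(lam[1], rel=1e-8)

    def test_sqrt_correction_reconstructs_distances(self, pool42):
        # random mixed-trait Gower matrix: after the sqrt transform the
        # full-rank embedding must reproduce the corrected distances
        sub = pool42.traits.iloc[:10]
        D = gower(sub)
        space = pcoa(D, correction="sqrt")
        assert space.correction == "sqrt"
        full = space.coordinates.to_numpy()
        np.testing.assert_allclose(
            pdist(full), squareform(np.sqrt(D.to_numpy()), checks=False), atol=1e-8
        )

    def test_cailliez_correction_removes_negative_eigenvalues(self, pool42):
        D = gower(pool42.traits.iloc[:12])
        space = pcoa(D, correction="cailliez")
        assert space.correction == "cailliez"
        assert (space.eigenvalues > 0).all()

    def test_uncorrected_records_warning_flag(self, pool42):
        D = gower(pool42.traits.iloc[:12])
        space = pcoa(D, correction="none")
        assert space.negative_eigenvalue_warning

    def test_matches_scikit_bio_reference(self):
        # independent oracle on a Euclidean (correction-free) matrix
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        D = _euclidean_D(pts)
        ours = pcoa(D)
        theirs = skbio_ordination.pcoa(D.to_numpy(), number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.axes(3)),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_percent_variation_sums_to_one_over_positive_axes(self, space42):
        assert space42.proportion_explained.sum() == pytest.approx(1.0)
        assert (np.diff(space42.eigenvalues) <= 1e-12).all()


class TestSpaceQuality:
    def test_exact_embedding_scores_zero(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        D = _euclidean_D(pts)
        space = pcoa(D)
        assert space_quality(D, space, 3) == pytest.approx(0.0, abs=1e-12)

    def test_profile_non_increasing_in_m(self, pool42, gower42):
        space = pcoa(gower42)
        profile = quality_profile(gower42, space, m_max=8)
        vals = list(profile.values())
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_five_point_toy_matches_hand_computation(self):
        pts = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.1, 0.0], [0.2, 1.0, 0.3],
             [0.9, 0.8, 0.6], [0.4, 0.3, 1.0]]
        )
        D = _euclidean_D(pts)
        space = pcoa(D)
        got = space_quality(D, space, 2)
        # independent pair-sum: rescale 2-axis distances to the max of D
        emb = space.axes(2)
        s, d = [], []
        for i in range(5):
            for j in range(i + 1, 5):
                s.append(np.sqrt(((emb[i] - emb[j]) ** 2).sum()))
                d.append(D.iloc[i, j])
        s = np.array(s) * (max(d) / max(s))
        expected = np.mean((s - np.array(d)) ** 2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_m_below_two_rejected(self, gower42):
        space = pcoa(gower42)
        with pytest.raises(ConfigError):
            space_quality(gower42, space, 1)


def _space_from_coords(pts, labels=None):
    labels = labels or [f"p{i}" for i in range(len(pts))]
    coords = pd.DataFrame(
        pts, index=labels, columns=[f"pcoa_{i+1}" for i in range(pts.shape[1])]
    )
    lam = np.ones(pts.shape[1])
    return FunctionalSpace(
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=lam / lam.sum(),
        correction="none",
        m=pts.shape[1],
    )


class TestHullVertices:
    def test_unit_square_with_centroid(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], dtype=float)
        space = _space_from_coords(pts, ["a", "b", "c", "d", "centre"])
        hull = hull_vertices(space, m=2)
        assert sorted(hull.vertices) == ["a", "b", "c", "d"]
        assert hull.non_vertices == ["centre"]
        assert hull.volume == pytest.approx(1.0)

    def test_regular_tetrahedron_volume(self):
        pts = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.5, np.sqrt(3) / 2, 0.0],
                [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
            ]
        )
        space = _space_from_coords(pts)
        hull = hull_vertices(space, m=3)
        assert hull.volume == pytest.approx(1 / (6 * np.sqrt(2)), rel=1e-10)

    def test_vertex_set_matches_lp_membership_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 4))
        space = _space_from_coords(pts)
        hull = hull_vertices(space, m=4)
        expected = {
            f"p{i}" for i in range(20) if is_hull_vertex_lp(pts, i)
        }
        assert set(hull.vertices) == expected

    def test_duplicate_points_deduplicated(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 0], [0.2, 0.2]], dtype=float)
        space = _space_from_coords(pts, ["a", "b", "c", "b_twin", "inner"])
        hull = hull_vertices(space, m=2)
        assert set(hull.vertices) == {"a", "b", "c", "b_twin"}

    def test_degenerate_sets_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        space = _space_from_coords(pts)
        with pytest.raises(DimensionalityError):
            hull_vertices(space, m=2)

    def test_hull_volume_monotone_under_species_addition(self, space42):
        rng = np.random.default_rng(9)
        species = list(space42.species)
        base = list(rng.choice(species, size=10, replace=False))
        rest = [s for s in species if s not in base]
        prev = hull_vertices(space42, base, m=4).volume
        for extra in range(3):
            base.append(rest[extra])
            vol = hull_vertices(space42, base, m=4).volume
            assert vol >= prev - 1e-12
            prev = vol
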