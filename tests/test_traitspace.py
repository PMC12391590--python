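"""Distance matrices, ordination spaces and quality scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import elevdiv as ed
from elevdiv.traitspace import log_z_scores, select_n_axes


def _morph(values, traits=("m1",)):
    return pd.DataFrame(values, columns=list(traits),
                        index=[f"sp{i}" for i in range(len(values))])


class TestMorphologicalDistance:
    def test_identical_species_have_zero_distance(self):
        m = _morph([[10.0, 5.0], [10.0, 5.0], [3.0, 8.0]], traits=("m1", "m2"))
        d = ed.morphological_distance(m)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_trait(self):
        # raw {e^1, e^3}: logs {1, 3}, sample-SD z-scores ±0.7071, distance 1.4142
        m = _morph([[np.e], [np.e**3]])
        d = ed.morphological_distance(m)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_symmetry_on_random_tables(self):
        rng = np.random.default_rng(0)
        m = _morph(rng.lognormal(size=(12, 5)), traits=[f"t{i}" for i in range(5)])
        d = ed.morphological_distance(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            ed.morphological_distance(_morph([[1.0], [-2.0]]))

    def test_zero_variance_trait_dropped_with_warning(self):
        m = _morph([[1.0, 5.0], [1.0, 9.0], [1.0, 2.0]], traits=("flat", "ok"))
        with pytest.warns(UserWarning, match="zero-variance"):
            d = ed.morphological_distance(m)
        assert d.to_numpy().max() > 0


class TestGowerDistance:
    def test_identical_profiles_zero(self):
        block = pd.DataFrame([[0.5, 0.5, 0.0]] * 2, index=["a", "b"])
        d = ed.gower_distance({"diet": block})
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_vertices_are_maximal(self):
        block = pd.DataFrame(
            [[1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0]], index=["a", "b"], dtype=float
        )
        d = ed.gower_distance({"diet": block})
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_bounded_for_dirichlet_rows(self):
        fuzzy = ed.simulate_fuzzy_traits(30, seed=2)
        blocks = {
            g: fuzzy[[c for c in fuzzy.columns if c.startswith(g + "_")]]
            for g in ("diet", "strata", "strategies")
        }
        d = ed.gower_distance(blocks).to_numpy()
        assert d.min() >= 0 and d.max() <= 1 + 1e-12

    def test_unnormalised_rows_rejected(self):
        block = pd.DataFrame([[0.5, 0.3], [0.6, 0.4]], index=["a", "b"])
        with pytest.raises(ValueError, match="not normalised"):
            ed.gower_distance({"diet": block})


class TestCombinedDistance:
    @pytest.fixture()
    def traits_and_manifest(self, small_dataset):
        return small_dataset.traits, small_dataset.manifest

    def test_morphology_only_weights(self, traits_and_manifest):
        traits, manifest = traits_and_manifest
        weights = {"morphology": 1.0, "diet": 0.0, "strata": 0.0, "strategies": 0.0}
        combined, _ = ed.combined_distance(traits, manifest, weights=weights)
        morph_cols = [c for c, m in manifest.items() if m["group"] == "morphology"]
        expect = squareform(pdist(log_z_scores(traits[morph_cols]).to_numpy()))
        expect /= expect.max()
        assert np.allclose(combined.to_numpy(), expect, atol=1e-12)

    def test_balanced_contributions_are_equal(self, traits_and_manifest):
        traits, manifest = traits_and_manifest
        combined, weights = ed.combined_distance(traits, manifest)
        # recompute per-block mean contributions under the returned weights
        groups = ed.traitspace.groups_from_manifest(manifest)
        contribs = []
        for g, cols in groups.items():
            if manifest[cols[0]]["type"] == "continuous":
                d = squareform(pdist(log_z_scores(traits[cols]).to_numpy()))
                d /= d.max()
            else:
                d = ed.gower_distance({g: traits[cols]}).to_numpy()
            iu = np.triu_indices(len(traits), 1)
            contribs.append(weights[g] * d[iu].mean())
        assert np.ptp(contribs) < 1e-4

    def test_identical_blocks_reproduce_single_block(self):
        block = pd.DataFrame(
            [[1, 0], [0, 1], [0.5, 0.5]], index=list("abc"),
            columns=["g1_x", "g1_y"], dtype=float,
        )
        manifest = {
            "g1_x": {"group": "g1", "type": "fuzzy"},
            "g1_y": {"group": "g1", "type": "fuzzy"},
            "g2_x": {"group": "g2", "type": "fuzzy"},
            "g2_y": {"group": "g2", "type": "fuzzy"},
        }
        traits = pd.concat(
            [block, block.rename(columns={"g1_x": "g2_x", "g1_y": "g2_y"})], axis=1
        )
        combined, _ = ed.combined_distance(traits, manifest)
        single = ed.gower_distance({"g1": block})
        assert np.allclose(combined.to_numpy(), single.to_numpy(), atol=1e-9)


class TestOrdination:
    def test_unit_square_embeds_exactly(self, unit_square):
        d = pd.DataFrame(squareform(pdist(unit_square)), index=list("abcd"),
                         columns=list("abcd"))
        space = ed.ordinate(d, method="pcoa", m_axes=2)
        assert space.quality.rmsd == pytest.approx(0.0, abs=1e-9)
        back = squareform(pdist(space.coordinates.to_numpy()))
        assert np.allclose(back, d.to_numpy(), atol=1e-9)

    def test_collinear_points_have_one_positive_eigenvalue(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = pd.DataFrame(squareform(pdist(pts)), index=list("abc"), columns=list("abc"))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            space = ed.ordinate(d, method="pcoa", m_axes=2)
        assert space.m_axes == 1

    def test_rmsd_non_increasing_in_axes(self, small_dataset):
        fuzzy_cols = [c for c in small_dataset.traits.columns if c.startswith("diet_")]
        d = ed.gower_distance({"diet": small_dataset.traits[fuzzy_cols]})
        rmsds = [
            ed.ordinate(d, method="pcoa", m_axes=m).quality.rmsd for m in range(1, 5)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmsds[:-1], rmsds[1:]))

    def test_pca_space_matches_euclidean_distances(self, small_dataset):
        raw = log_z_scores(small_dataset.morphology)
        space = ed.ordinate(raw, method="pca", m_axes=5)
        back = squareform(pdist(space.coordinates.to_numpy()))
        assert np.allclose(back, squareform(pdist(raw.to_numpy())), atol=1e-9)
        assert space.quality.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_select_n_axes_respects_cap(self, small_dataset):
        fuzzy_cols = [c for c in small_dataset.traits.columns if c.startswith("strata_")]
        d = ed.gower_distance({"strata": small_dataset.traits[fuzzy_cols]})
        m = select_n_axes(d, method="pcoa", max_axes=3)
        assert 1 <= m <= 3


class TestSpaceQuality:
    def test_exact_embedding_scores_zero(self, unit_square):
        d = pd.DataFrame(squareform(pdist(unit_square)), index=list("abcd"),
                         columns=list("abcd"))
        space = ed.ordinate(d, method="pcoa", m_axes=2)
        q = ed.space_quality(d, space)
        assert q.mad == pytest.approx(0.0, abs=1e-9)
        assert q.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_deviations(self):
        pts = np.array([[0.0], [1.0], [3.0]])  # in-space pair distances 1, 3, 2
        d_in = pd.DataFrame(
            squareform(np.array([1.0, 2.0, 2.0])), index=list("abc"), columns=list("abc")
        )
        space = ed.TraitSpace(
            name="x",
            coordinates=pd.DataFrame(pts, index=list("abc"), columns=["axis_1"]),
            eigenvalues=np.array([1.0]),
            method="pcoa",
        )
        # in-space distances 1, 3, 2 vs inputs 1, 2, 2: deviations {0, 1, 0}
        q = ed.space_quality(d_in, space)
        assert q.mad == pytest.approx(1 / 3)
        assert q.rmsd == pytest.approx(np.sqrt(1 / 3))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rmsd_at_least_mad(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        d = pd.DataFrame(
            squareform(pdist(pts)) * rng.uniform(0.5, 1.5),
            index=[f"s{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(8)],
        )
        d = pd.DataFrame((d.to_numpy() + d.to_numpy().T) / 2, index=d.index, columns=d.columns)
        np.fill_diagonal(d.values, 0.0)
        space = ed.ordinate(d, method="pcoa", m_axes=2)
        q = space.quality
        assert q.rmsd >= q.mad - 1e-12
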