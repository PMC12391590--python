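"""Synthetic generators: tree, Brownian traits, fuzzy traits, ranges, scenarios."""

import numpy as np
import pytest

import elevdiv as ed
from elevdiv.traitspace import log_z_scores


def _newick(tree):
    return tree.as_string(schema="newick")


class TestSimulateTree:
    def test_smallest_tree(self):
        tree = ed.simulate_tree(2, 1.0, seed=5)
        assert len(tree.leaf_nodes()) == 2
        assert sum(1 for n in tree if not n.is_leaf()) == 1

    def test_bifurcating_node_count(self):
        tree = ed.simulate_tree(8, 1.0, seed=5)
        assert len(tree.leaf_nodes()) == 8
        assert sum(1 for n in tree if not n.is_leaf()) == 7  # 2n-1 nodes total
        assert all(len(n.child_nodes()) == 2 for n in tree if not n.is_leaf())

    def test_seed_determinism(self):
        a = ed.simulate_tree(50, 1.0, seed=123)
        b = ed.simulate_tree(50, 1.0, seed=123)
        assert _newick(a) == _newick(b)
        c = ed.simulate_tree(50, 1.0, seed=124)
        assert _newick(a) != _newick(c)

    def test_branch_lengths_positive(self):
        tree = ed.simulate_tree(40, 2.0, seed=9)
        lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
        assert len(lengths) == 2 * 40 - 2
        assert min(lengths) > 0

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            ed.simulate_tree(1, 1.0, seed=0)


class TestSimulateBmTraits:
    def test_zero_rate_keeps_root_value(self):
        tree = ed.simulate_tree(10, 1.0, seed=2)
        traits = ed.simulate_bm_traits(tree, n_traits=3, bm_sigma=0.0, seed=2)
        assert np.allclose(traits.to_numpy(), 0.0)

    def test_variance_scales_with_rate(self):
        tree = ed.simulate_tree(64, 1.0, seed=3)
        lo = ed.simulate_bm_traits(tree, n_traits=50, bm_sigma=0.5, seed=3).to_numpy()
        hi = ed.simulate_bm_traits(tree, n_traits=50, bm_sigma=2.0, seed=3).to_numpy()
        assert hi.var() > lo.var() * 4  # 16x expected

    def test_zero_depth_tree_rejected(self, tiny_tree):
        for e in tiny_tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
        with pytest.raises(ValueError, match="depth"):
            ed.simulate_bm_traits(tiny_tree, 2, 1.0, seed=0)


class TestSimulateFuzzyTraits:
    def test_rows_sum_to_one_per_group(self):
        out = ed.simulate_fuzzy_traits(25, seed=4)
        for group, axes in ed.simulate.DEFAULT_FUZZY_AXES.items():
            cols = [f"{group}_{a}" for a in axes]
            sums = out[cols].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)
        assert ((out >= 0) & (out <= 1)).all().all()

    def test_large_alpha_approaches_uniform(self):
        out = ed.simulate_fuzzy_traits(
            200, {"diet": 5000.0, "strata": 5000.0, "strategies": 5000.0}, seed=4
        )
        diet = out[[c for c in out.columns if c.startswith("diet_")]].to_numpy()
        assert np.abs(diet - 1 / 6).max() < 0.05

    def test_small_alpha_concentrates_on_vertices(self):
        out = ed.simulate_fuzzy_traits(
            200, {"diet": 0.1, "strata": 0.1, "strategies": 0.1}, seed=4
        )
        diet = out[[c for c in out.columns if c.startswith("diet_")]].to_numpy()
        uniform = ed.simulate_fuzzy_traits(
            200, {"diet": 20.0, "strata": 20.0, "strategies": 20.0}, seed=4
        )
        udiet = uniform[[c for c in uniform.columns if c.startswith("diet_")]].to_numpy()
        assert np.median(diet.max(axis=1)) > 0.75
        assert np.median(diet.max(axis=1)) > 2 * np.median(udiet.max(axis=1))

    def test_non_positive_alpha_rejected(self):
        with pytest.raises(ValueError):
            ed.simulate_fuzzy_traits(10, {"diet": -1.0}, seed=0)


class TestSimulateRanges:
    def _band_richness(self, ranges, bands):
        lo = ranges["min_elev"].to_numpy()
        hi = ranges["max_elev"].to_numpy()
        return np.array([((hi >= b.lower) & (lo < b.upper)).sum() for b in bands])

    def test_ranges_within_gradient_and_occupy_a_band(self, gradient_bands):
        cfg = ed.SimulationConfig(n_species=80, seed=1)
        ranges = ed.simulate_ranges(cfg)
        assert (ranges["min_elev"] >= cfg.elevation_min).all()
        assert (ranges["max_elev"] <= cfg.elevation_max).all()
        assert (ranges["min_elev"] <= ranges["max_elev"]).all()
        occ = ed.assemble(ranges, gradient_bands)
        assert set(occ.species) == set(ranges.index)

    def test_flat_gradient_has_no_band_trend(self, gradient_bands):
        # mean per-band richness over 300 replicates: edge bands must not
        # systematically differ from interior bands beyond sampling noise
        total = np.zeros(len(gradient_bands))
        n_rep = 300
        for s in range(n_rep):
            cfg = ed.SimulationConfig(n_species=100, richness_gradient=0.0, seed=s)
            total += self._band_richness(ed.simulate_ranges(cfg), gradient_bands)
        means = total / n_rep
        # binomial SE per band mean is ~0.3; allow 4 SE spread around the grand mean
        assert np.abs(means - means.mean()).max() < 1.5

    def test_strong_gradient_orders_extreme_bands(self, gradient_bands):
        wins = 0
        for s in range(200):
            cfg = ed.SimulationConfig(n_species=100, richness_gradient=4.0, seed=s)
            r = self._band_richness(ed.simulate_ranges(cfg), gradient_bands)
            wins += r[0] > r[-1]
        assert wins / 200 >= 0.95

    def test_expected_richness_declines_with_gradient(self, gradient_bands):
        total = np.zeros(len(gradient_bands))
        for s in range(200):
            cfg = ed.SimulationConfig(n_species=100, richness_gradient=1.5, seed=s)
            total += self._band_richness(ed.simulate_ranges(cfg), gradient_bands)
        means = total / 200
        assert (np.diff(means) < 0).all()


class TestTraitScenarios:
    def test_neutral_is_identity(self, small_dataset, small_occ):
        morph = small_dataset.morphology
        out = ed.apply_trait_scenario(morph, small_occ, "neutral", 5.0, seed=1)
        assert out.equals(morph)

    def test_unknown_scenario_rejected(self, small_dataset, small_occ):
        with pytest.raises(ValueError, match="scenario"):
            ed.apply_trait_scenario(small_dataset.morphology, small_occ, "magic", 1.0)

    def test_filtering_shrinks_within_band_nn_distances(self, small_dataset, small_occ):
        morph = small_dataset.morphology
        filtered = ed.apply_trait_scenario(morph, small_occ, "filtering", 0.8, seed=3)
        base = log_z_scores(morph).to_numpy()
        filt = log_z_scores(filtered).to_numpy()

        def mean_band_fnnd(z):
            vals = []
            for b in small_occ.band_labels:
                idx = small_occ.species_indices(b, morph.index)
                if len(idx) >= 2:
                    vals.append(ed.fnnd(points=z[idx]))
            return np.mean(vals)

        assert mean_band_fnnd(filt) < mean_band_fnnd(base)

    def test_limiting_similarity_removes_close_pairs(self, small_dataset, small_occ):
        morph = small_dataset.morphology
        spread = ed.apply_trait_scenario(
            morph, small_occ, "limiting_similarity", 2.0, seed=3
        )
        z = log_z_scores(spread).to_numpy()
        mins = []
        for b in small_occ.band_labels:
            idx = small_occ.species_indices(b, morph.index)
            if len(idx) >= 2:
                sub = z[idx]
                d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                mins.append(d.min())
        z0 = log_z_scores(morph).to_numpy()
        mins0 = []
        for b in small_occ.band_labels:
            idx = small_occ.species_indices(b, morph.index)
            if len(idx) >= 2:
                sub = z0[idx]
                d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                mins0.append(d.min())
        assert min(mins) > min(mins0)

    def test_positivity_preserved(self, small_dataset, small_occ):
        for scen, strength in [("filtering", 0.8), ("limiting_similarity", 2.0)]:
            out = ed.apply_trait_scenario(
                small_dataset.morphology, small_occ, scen, strength, seed=7
            )
            assert (out.to_numpy() > 0).all()


class TestDatasetDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = ed.SimulationConfig(n_species=20, trait_scenario="filtering",
                                  scenario_strength=0.5, seed=42)
        a = ed.simulate_dataset(cfg)
        b = ed.simulate_dataset(cfg)
        assert a.ranges.equals(b.ranges)
        assert a.traits.equals(b.traits)
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")

    def test_written_bundle_round_trips(self, tmp_path):
        cfg = ed.SimulationConfig(n_species=12, seed=8)
        ds = ed.simulate_dataset(cfg)
        paths = ed.write_dataset(ds, tmp_path)
        assert sorted(p.name for p in tmp_path.iterdir()) == sorted(
            p.name for p in paths.values()
        )
        reloaded = ed.read_tree(paths["tree"])
        assert len(reloaded.leaf_nodes()) == 12
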