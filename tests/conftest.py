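import dendropy
import numpy as np
import pandas as pd
import pytest

import elevdiv as ed


@pytest.fixture(scope="session")
def gradient_bands():
    """The 10 half-open 200-m bands tiling 350-2350 m."""
    return ed.build_bands(350, 2350, 200)


@pytest.fixture()
def tiny_tree():
    """((A:1,B:1):1,C:2); — AB=2, AC=BC=4 patristic."""
    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture()
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-species neutral synthetic study shared by read-only tests."""
    return ed.simulate_dataset(ed.SimulationConfig(n_species=30, seed=11))


@pytest.fixture(scope="session")
def small_occ(small_dataset, gradient_bands):
    return ed.assemble(small_dataset.ranges, gradient_bands)


@pytest.fixture()
def fuzzy_manifest():
    """Manifest for a two-group fuzzy trait table used in guild tests."""
    cols = {
        "diet_invertebrates": "diet",
        "diet_fruits": "diet",
        "diet_seeds": "diet",
        "strata_ground": "strata",
        "strata_canopy": "strata",
    }
    return {c: {"group": g, "type": "fuzzy"} for c, g in cols.items()}


def make_ranges(entries) -> pd.DataFrame:
    """Helper: ranges frame from {species: (min, max)}."""
    return pd.DataFrame(
        {
            "species": list(entries),
            "min_elev": [v[0] for v in entries.values()],
            "max_elev": [v[1] for v in entries.values()],
        }
    ).set_index("species")
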