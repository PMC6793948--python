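import numpy as np
import pandas as pd
import pytest

import patchscape as ps


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mixed_traits():
    """Five species, one trait of each scale, one missing cell."""
    values = pd.DataFrame(
        {
            "height": [2.0, 7.0, 12.0, np.nan, 5.0],
            "clonal": [0, 1, 1, 0, 1],
            "flower_month": [3, 5, 5, 8, 3],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="species_id"),
    )
    meta = pd.DataFrame(
        {
            "block": ["vegetative", "vegetative", "phenology"],
            "scale": ["continuous", "binary", "ordinal"],
            "lo": [np.nan, 0, 3],
            "hi": [np.nan, 1, 10],
        },
        index=pd.Index(["height", "clonal", "flower_month"], name="trait"),
    )
    return ps.TraitTable(values, meta)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = ps.SimConfig(n_patches=60, n_species=25, n_background_pgh=40)
    return ps.generate_study(cfg, seed=7)


def random_trait_table(rng, n_species, n_traits, missing_rate=0.1):
    """Random mixed-type trait table (uniform over the three scales)."""
    scales = rng.choice(["continuous", "binary", "ordinal"], size=n_traits)
    values = {}
    meta_rows = []
    for t, scale in enumerate(scales):
        name = f"t{t}"
        if scale == "continuous":
            col = rng.normal(size=n_species) * 10
            lo = hi = np.nan
        elif scale == "binary":
            col = rng.integers(0, 2, size=n_species).astype(float)
            lo, hi = 0, 1
        else:
            col = rng.integers(1, 6, size=n_species).astype(float)
            lo, hi = 1, 5
        mask = rng.random(n_species) < missing_rate
        col = np.where(mask, np.nan, col)
        values[name] = col
        meta_rows.append({"trait": name, "block": "vegetative", "scale": scale,
                          "lo": lo, "hi": hi})
    vdf = pd.DataFrame(values,
                       index=pd.Index([f"s{i}" for i in range(n_species)],
                                      name="species_id"))
    meta = pd.DataFrame(meta_rows).set_index("trait")
    return ps.TraitTable(vdf, meta)
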