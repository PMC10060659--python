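import numpy as np
import pandas as pd
import pytest

from redunet import FunctionalCatalogConfig, GeneCatalog, SyntheticDesign, generate


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic noise-free community: construction facts are exact."""
    design = SyntheticDesign(sigma=0.0, species_sigma=0.0, community_sigma=0.0,
                             pathway_sigma=0.0, seed=1)
    return design, *generate(design)


@pytest.fixture(scope="session")
def default_dataset():
    """One default (noisy) synthetic dataset shared across tests."""
    design = SyntheticDesign(seed=42)
    return design, *generate(design)


@pytest.fixture()
def tiny_catalog():
    frame = pd.DataFrame(
        {
            "species": ["sp1", "sp1", "sp2", "sp2", "sp3"],
            "category": ["CatA", "CatB", "CatA", "CatB", "CatB"],
            "pathway": ["p1", "p2", "p1", "p2", "p2"],
            "length_bp": [500, 1000, 1500, 2000, 800],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )
    return GeneCatalog(frame)


@pytest.fixture()
def tiny_config():
    return FunctionalCatalogConfig({"CatA": "broad", "CatB": "specialized"})
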