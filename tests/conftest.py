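import numpy as np
import pandas as pd
import pytest

from turftraits.data_model import TRAIT_COLUMNS
from turftraits.synthetic_data import SimulationConfig, simulate_dataset


def make_trait_rows(rows):
    """Build a trait table from compact (species, site, plot, treatment, trait,
    value) tuples, filling taxonomy and ids mechanically."""
    out = []
    for i, (species, site, plot_id, treatment, trait, value) in enumerate(rows):
        genus = species.rsplit("_", 1)[0] if "_" in species else f"g_{species}"
        out.append(
            {
                "leaf_id": f"L{i}",
                "species": species,
                "genus": genus,
                "family": f"f_{genus}",
                "order": f"o_{genus}",
                "site": site,
                "plot_id": plot_id,
                "block": plot_id.rsplit("-", 1)[0] if "-" in plot_id else "",
                "treatment": treatment,
                "origin_site": site,
                "trait": trait,
                "value": float(value),
            }
        )
    return pd.DataFrame(out, columns=list(TRAIT_COLUMNS))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_orders=2, families_per_order=2, genera_per_family=2,
        species_per_genus=2, n_sites=3, n_blocks=2, n_focal_species=6,
        leaves_per_species_site=5, traits=("SLA", "LDMC"), seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
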