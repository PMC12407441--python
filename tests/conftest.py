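import numpy as np
import pandas as pd
import pytest

from pullnet.assoc_map import resolve_metabolites
from pullnet.synthetic_data import (
    SimulationConfig,
    generate_associations,
    generate_interactome,
)


@pytest.fixture(scope="session")
def small_sim():
    """A fast, fully generated synthetic study shared across tests."""
    sim = SimulationConfig(rng_seed=42)
    interactome, truth = generate_interactome(sim)
    associations = generate_associations(truth, sim)
    queries = sorted({r.metabolite_id for r in associations.rows})
    seed_map = resolve_metabolites(queries, associations)
    return {
        "sim": sim,
        "interactome": interactome,
        "truth": truth,
        "associations": associations,
        "seed_map": seed_map,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_metabolite_frame(values, sample_prefix="S", met_prefix="m"):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{sample_prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"{met_prefix}{j}" for j in range(arr.shape[1])],
    )
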