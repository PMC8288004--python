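import warnings

import numpy as np
import pandas as pd
import pytest

from adaptscape.genotypes import GenotypeMatrix
from adaptscape.simulate import (SimConfig, default_landscape,
                                 default_pair_configs, sample_sites,
                                 simulate_genotypes, simulate_pair)
from adaptscape.climate import extract_at_points

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def landscape():
    return default_landscape(seed=11)


@pytest.fixture(scope="session")
def sim_species(landscape):
    """One seeded species data set: 10 pops x 12 ind, 400 neutral + 6 adaptive."""
    samples = sample_sites(landscape, 10, (12, 12), seed=11)
    table = extract_at_points(landscape, samples)
    cfg = SimConfig(n_pops=10, n_ind_per_pop=(12, 12), n_neutral=400,
                    n_adaptive=6,
                    driver_map={k: "temp_seasonality" for k in range(6)},
                    effect_beta=3.0, fst_target=0.2, seed=11)
    g, truth = simulate_genotypes(samples, table.values, cfg)
    return {"genotypes": g, "truth": truth, "samples": samples,
            "climate": table, "config": cfg}


@pytest.fixture(scope="session")
def sim_pair_small():
    host_cfg, par_cfg = default_pair_configs(seed=5, n_neutral=300, n_adaptive=6)
    return simulate_pair(host_cfg, par_cfg, shared_seed=5)


@pytest.fixture
def toy_genotypes():
    """Hand-sized matrix: 6 individuals in 2 populations, 4 loci."""
    counts = np.array([
        [0, 1, 2, 0],
        [1, 1, 2, 0],
        [0, 2, 1, 0],
        [2, 0, 0, 1],
        [1, 0, 0, 0],
        [2, 1, 1, 0],
    ], dtype=np.int16)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "population": ["A"] * 3 + ["B"] * 3,
        "lon": [116.1, 116.2, 116.3, 118.1, 118.2, 118.3],
        "lat": [-31.0, -31.1, -31.2, -28.0, -28.1, -28.2],
    })
    loci = pd.DataFrame({
        "locus_id": [f"L{j}" for j in range(4)],
        "fragment_id": ["f0", "f0", "f1", "f2"],
        "reproducibility": [1.0, 1.0, 0.99, 1.0],
    })
    return GenotypeMatrix(counts=counts, samples=samples, loci=loci)
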