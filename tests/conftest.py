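import numpy as np
import pytest

import poolqtl as pq


@pytest.fixture(scope="session")
def tiny_map() -> pq.MarkerMap:
    """Two small chromosomes with irregular marker spacing."""
    return pq.MarkerMap(
        chromosomes=[("chrA", 50_000), ("chrB", 40_000)],
        markers={"chrA": np.array([1_000, 3_200, 10_000, 25_000, 49_000]),
                 "chrB": np.array([500, 20_000, 39_500])})


@pytest.fixture(scope="session")
def desk_map() -> pq.MarkerMap:
    return pq.desk_genome()


@pytest.fixture(scope="session")
def small_experiment(desk_map):
    """One desk-scale two-replicate experiment with a strong planted QTL.

    Shared across tests that only need some mapped output; returns the
    architecture, the per-replicate (lod, daf, qtls) scans, and the
    replicate-concordant calls.
    """
    arch = pq.QTLArchitecture(
        loci=[pq.QTLLocus("chr03", 40_000, 1.2),
              pq.QTLLocus("chr07", 25_000, -1.0)],
        noise_sd=1.0)
    sim = pq.SimulationConfig(n_segregants=30_000, architecture=arch)
    per_rep, concordant = pq.map_experiment(desk_map, sim, pq.MappingConfig(),
                                            seed=424242)
    return arch, sim, per_rep, concordant
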