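import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import timbertrace as tt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_pops():
    return tt.malaysia_reference_populations()


@pytest.fixture(scope="session")
def two_pop_table():
    """A tiny two-population metadata table spanning both regions."""
    frame = pd.DataFrame(
        dict(
            code=[1, 2],
            name=["WestPop", "EastPop"],
            region=["Western", "Eastern"],
        )
    )
    return tt.PopulationTable(frame)


def make_table(loci, rows, populations):
    """Build an STRGenotypeTable from (id, pop, flat allele list) rows."""
    individuals = [r[0] for r in rows]
    pops = np.array([r[1] for r in rows], dtype=np.int64)
    calls = np.array([r[2] for r in rows], dtype=np.int64).reshape(len(rows), len(loci), 2)
    return tt.STRGenotypeTable(individuals, list(loci), calls, pops, populations)


@pytest.fixture(scope="session")
def default_sim():
    """One default-design simulation shared across the suite."""
    config = tt.SimulationConfig(seed=11)
    return tt.simulate_str_dataset(config)


@pytest.fixture(scope="session")
def cp_sim(ref_pops):
    alignments, truth = tt.simulate_cpdna_dataset(seed=11, populations=ref_pops)
    matrix = tt.extract_variable_sites(alignments)
    db = tt.collapse_haplotypes(matrix, truth["sample_populations"], ref_pops)
    return alignments, truth, matrix, db
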