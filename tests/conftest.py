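import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncpipe import simulate as sim
from lncpipe.pipeline import run_pipeline


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset with planted triplex sites (seed 1)."""
    ds = sim.generate_genome_annotation(seed=1)
    sim.plant_triplex_sites(ds, seed=1, n_sites=3)
    return ds


@pytest.fixture(scope="session")
def tables(dataset):
    return sim.simulate_expression(dataset, seed=1)


@pytest.fixture(scope="session")
def pipeline_result(dataset, tables):
    return run_pipeline(
        dataset.candidates,
        dataset.reference,
        dataset.genome,
        tables["counts"],
        tables["design"],
        de_table=tables["de_table"],
        hits=dataset.hits,
    )
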