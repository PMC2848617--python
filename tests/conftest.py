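import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from appia import pipeline, synthetic

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_WORLD_CONFIG = synthetic.WorldConfig(
    seed=7,
    n_genomes=20,
    n_proteins=60,
    n_positive_pairs=15,
    n_regulons=2,
    fusion_prob=0.5,
    presence_prob=0.75,
)


@pytest.fixture(scope="session")
def small_world():
    return synthetic.generate_world(SMALL_WORLD_CONFIG)


@pytest.fixture(scope="session")
def small_world_result(small_world):
    w = small_world
    inputs = pipeline.PipelineInputs(
        table=w.table,
        coordinates=w.coordinates,
        alignments=w.alignments,
        gf=w.gf,
        positives=w.positives,
        protein_lengths=w.protein_lengths,
    )
    params = pipeline.RunParams(min_per_band=5, min_common=8)
    return pipeline.run_core(inputs, params, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
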