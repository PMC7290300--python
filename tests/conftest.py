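"""Shared fixtures: one mid-sized truth set and its processed control library.

Problem sizes are deliberately small (tens of kb of genome, ~10k reads) so
the whole suite runs in minutes on one CPU while still exercising every
pipeline stage on data with planted ground truth.
"""

import pytest

from mirdeg import pipeline, synthetic

SMALL_CFG = synthetic.GeneratorConfig(n_mir=4, genome_size=20_000, depth=15_000)
TINY_CFG = synthetic.GeneratorConfig(n_mir=3, genome_size=12_000, depth=8_000)


@pytest.fixture(scope="session")
def truth():
    return synthetic.generate_truth(SMALL_CFG, seed=11)


@pytest.fixture(scope="session")
def control_result(truth):
    reads = synthetic.simulate_srna_library(truth, "control_70SWC", 1, seed=11)
    return pipeline.run_srna_pipeline(
        reads, truth.config.adapter, truth.genome, "control_r1"
    )


@pytest.fixture(scope="session")
def tiny_truth():
    return synthetic.generate_truth(TINY_CFG, seed=4)
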