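import time

import numpy as np
import pytest
from hypothesis import settings

from hetnuc.genome import Chromosome, GenomeModel, Interval
from hetnuc.pipeline import run_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel(
        [
            Chromosome("a1", 3000, "autosome"),
            Chromosome("a2", 3000, "autosome"),
            Chromosome("x", 2000, "X"),
            Chromosome("y", 2000, "neoY"),
        ],
        pericentric=[Interval("a1", 0, 500), Interval("y", 0, 2000)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration run shared by the acceptance checks."""
    outdir = tmp_path_factory.mktemp("pipeline")
    t0 = time.time()
    results = run_pipeline(outdir, seed=11)
    elapsed = time.time() - t0
    return results, outdir, elapsed
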