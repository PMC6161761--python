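import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from cnepairs.io import GenomicInterval, SignalTrack
from cnepairs.pipeline import run_all
from cnepairs.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_track():
    """Constant fold-enrichment 3.0 over chr1:[0, 100000)."""
    return SignalTrack("t1", "H3K27ac",
                       [(GenomicInterval("chr1", 0, 100_000), 3.0)])


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One shared end-to-end pipeline run on a small synthetic dataset."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    config = SimConfig(seed=11, n_pairs=60, n_tissues=2)
    run_all(config, outdir, n_rep=20)
    return config, outdir
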