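import pytest

from splicekit import synthetic_fixtures as synth
from splicekit.workflow import run_training_pipeline


@pytest.fixture(scope="session")
def tiny_sim():
    """Small planted genome for cheap structural tests."""
    cfg = synth.SyntheticConfig(
        n_chromosomes=2, chrom_length=40_000, n_genes=24, exons_per_gene=3, seed=11
    )
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def default_pipeline():
    """Full train/calibrate/score pipeline on the default fixture (seed 1).

    Shared across model-quality, scan and end-to-end tests so the CNN is
    trained only once per session.
    """
    return run_training_pipeline(seed=1)
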