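import numpy as np
import pytest

from spongetrace import (
    AnalysisConfig,
    TruthSpec,
    inputs_from_bundle,
    run_pipeline,
    simulate_bundle,
)

BASES = np.array(list("ACGU"))


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: planted triplet, 50 decoys per class,
    log2 noise SD 0.25, 3 samples per group, fixed seed."""
    return simulate_bundle(TruthSpec())


@pytest.fixture(scope="session")
def default_report(default_bundle):
    """End-to-end pipeline run on the default bundle."""
    return run_pipeline(AnalysisConfig(), inputs_from_bundle(default_bundle))


@pytest.fixture(scope="session")
def small_bundle():
    """A down-scaled bundle for fast CLI / IO round-trip tests."""
    spec = TruthSpec(
        n_decoys_per_class=3,
        n_background=10,
        lncrna_length=600,
        utr_length=300,
        qpcr_n_per_group=4,
        rng_seed=7,
    )
    return simulate_bundle(spec)


@pytest.fixture()
def config():
    return AnalysisConfig()
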