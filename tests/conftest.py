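import logging

import numpy as np
import pytest

from methdelta.simulate import SyntheticConfig, generate_cohort, generate_manifest

logging.getLogger("methdelta").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced cohort: full structure, quick to generate and analyze."""
    return SyntheticConfig(
        n_baseline=60, n_first=24, n_second=20, n_all_three=12,
        n_background_cpgs=1500, n_batches=4, n_signature_probes=140,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    manifest = generate_manifest(small_config)
    matrix, sheet, reference, truth = generate_cohort(small_config, manifest)
    return {
        "config": small_config, "manifest": manifest, "matrix": matrix,
        "sheet": sheet, "reference": reference, "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
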