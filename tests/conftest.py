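import numpy as np
import pandas as pd
import pytest

from otomir.synthetic import CohortConfig, PlantedEffects, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-size cohort (11 roller + 6 spray + 17 controls), 120 genes."""
    cfg = CohortConfig(seed=42)
    effects = PlantedEffects.default(n_extra_de=44)
    return generate_cohort(cfg, effects, n_genes=120, mean_depth=5e5)


@pytest.fixture(scope="session")
def exposed_ids(small_cohort):
    return [s.id for s in small_cohort["subjects"] if s.group != "control"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
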