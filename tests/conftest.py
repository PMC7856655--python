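import numpy as np
import pytest

import scnwta as sw


@pytest.fixture(scope="session")
def small_setup():
    """A 16^3 cohort with default (moderate-coupling) parameters."""
    cfg = sw.GeneratorConfig(grid=(16, 16, 16), n_per_group=24, seed=11)
    atlas, truth = sw.generate_atlas(cfg)
    ds, cohort = sw.generate_cohort(cfg, atlas, truth)
    return cfg, atlas, truth, ds


@pytest.fixture(scope="session")
def coupled_setup():
    """A 32^3 cohort with strong subcortical coupling (signal >> noise)."""
    w0 = {("HC", s, l): 0.12 for s in ("striatum", "thalamus", "cerebellum")
          for l in range(1, 6)}
    cfg = sw.GeneratorConfig(grid=(32, 32, 32), n_per_group=40, seed=7,
                             coupling_w0=w0, coupling_w0_default=0.12,
                             noise_sd=0.02)
    atlas, truth = sw.generate_atlas(cfg)
    ds, cohort = sw.generate_cohort(cfg, atlas, truth)
    return cfg, atlas, truth, ds


@pytest.fixture
def rng():
    return np.random.default_rng(123)
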