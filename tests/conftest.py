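"""Shared fixtures: synthetic structures and reduced pipeline settings.

All geometry is generated at test time; the reduced configs shrink sample
counts and patch grids so the whole suite stays desk-scale while touching
every pipeline stage.
"""

import numpy as np
import pytest

from dimerface import make_planar_slab_dimer, run_structure
from dimerface.bayes import EffectSizeConfig
from dimerface.pipeline import CategoryConfig


@pytest.fixture(scope="session")
def slab():
    """Default tightly-packed planar slab dimer with its ground truth."""
    return make_planar_slab_dimer(seed=1)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced pipeline config: all stages active, small sample counts."""
    return CategoryConfig(
        patch_sizes=(3, 9),
        n_points=240,
        roughness_n_points=60,
        roughness_probes=tuple(np.round(np.arange(0.4, 4.01, 0.4), 10)),
        sampler=EffectSizeConfig(n_walkers=16, n_warmup=300, n_draws=300),
        seed=1,
    )


@pytest.fixture(scope="session")
def slab_result(slab, fast_config):
    dimer, _ = slab
    return run_structure(dimer, fast_config)


@pytest.fixture(scope="session")
def fast_sampler():
    return EffectSizeConfig(n_walkers=16, n_warmup=300, n_draws=300, seed=0)
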