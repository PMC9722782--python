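"""Shared fixtures: small phantom configurations and realized federations.

All data is generated programmatically; nothing is read from disk except
what a test itself writes to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from gliofed import (
    AugmentConfig,
    PhantomConfig,
    SiteSpec,
    generate_federation,
    prepare_dataset,
    tiny_config,
)


@pytest.fixture(scope="session")
def phantom_cfg() -> PhantomConfig:
    """Small phantoms (32^3) so whole federations run in seconds."""
    return PhantomConfig(volume_shape=(32, 32, 32), ed_radius_range=(7.5, 9.0))


@pytest.fixture(scope="session")
def model_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def aug_cfg() -> AugmentConfig:
    return AugmentConfig()


@pytest.fixture(scope="session")
def two_site_dataset(phantom_cfg):
    """A prepared (cropped + z-scored) 2-site federation, 4 + 3 cases."""
    specs = [SiteSpec("sA", 4), SiteSpec("sB", 3)]
    return prepare_dataset(generate_federation(specs, phantom_cfg, seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
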