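"""Shared fixtures: small, fast synthetic scenes for unit tests.

Unit tests use a reduced grid and channel mix; the acceptance suite uses
the full 24x42x384 defaults.
"""

import numpy as np
import pytest

from specseg import ChannelMixSpec, SceneSpec, make_feature_map, make_scene


SMALL_MIX = ChannelMixSpec(
    n_signal=30,
    n_fg_signal=8,
    n_bg_signal=8,
    n_noise=12,
    n_lowstd=6,
    n_irregular=4,
    seed=5,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 12x16 3-instance scene with a reduced channel mix."""
    spec = SceneSpec(height=12, width=16, k_instances=3, min_instance_fraction=0.08, seed=5)
    gt, fg = make_scene(spec)
    fmap, manifest = make_feature_map(gt, SMALL_MIX)
    return {"gt": gt, "fg": fg, "features": fmap, "manifest": manifest, "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
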