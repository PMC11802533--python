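"""Shared fixtures: fast-kinetics phantoms sized for unit tests."""

import numpy as np
import pytest

from perfdiff.phantom import BolusParams, PhantomConfig, generate_series

# compressed bolus timing so short series still contain all three peaks
FAST_KINETICS = dict(
    rv_bolus=BolusParams(onset=2.0, shape=2.0, scale=1.0, amplitude=1.0, baseline=0.10),
    lv_bolus=BolusParams(onset=4.0, shape=2.0, scale=1.0, amplitude=0.90, baseline=0.10),
    myo_bolus=BolusParams(onset=6.0, shape=2.0, scale=1.5, amplitude=0.35, baseline=0.10),
)


def fast_config(matrix_size=32, n_frames=14, seed=0, **kw) -> PhantomConfig:
    params = {**FAST_KINETICS, **kw}
    return PhantomConfig(matrix_size=matrix_size, n_frames=n_frames, seed=seed, **params)


@pytest.fixture(scope="session")
def small_series():
    """A 32x32, 14-frame phantom series with masks (shared, treat as read-only)."""
    return generate_series(fast_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
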