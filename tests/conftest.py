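import numpy as np
import pytest

from chronodcm import DCMParams, FrequencyGrid


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def grid16():
    return FrequencyGrid(np.linspace(0.01, 0.2, 16))


@pytest.fixture
def random_params(rng):
    """A stable random 4-ROI parameter set, drawn once per test."""

    def make(n_rois: int = 4, seed: int | None = None) -> DCMParams:
        r = np.random.default_rng(seed) if seed is not None else rng
        for _ in range(64):
            p = DCMParams(
                a_offdiag=r.uniform(-0.25, 0.25, (n_rois, n_rois)),
                a_self=r.normal(0, 0.1, n_rois),
                transit=r.normal(0, 0.1, n_rois),
                decay=r.normal(0, 0.05),
                epsilon=r.normal(0, 0.05),
                alpha_v=r.normal(0, 0.1),
                beta_v=r.normal(0, 0.05),
                alpha_e=r.normal(0, 0.1),
                beta_e=r.normal(0, 0.05),
            )
            if p.is_stable(0.05):
                return p
        raise RuntimeError("no stable draw")

    return make
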