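import numpy as np
import pytest


@pytest.fixture
def disc_mask():
    """Boolean disc mask factory: disc of given radius (px) centered in a grid."""
    def make(shape=(40, 40), radius_px=6.0, center=None):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        if center is None:
            center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
        return np.hypot(yy - center[0], xx - center[1]) <= radius_px
    return make


def make_growth_spec(**overrides):
    """Small valid tumor growth spec used across tests."""
    from glioscope.synth import TumorGrowthSpec

    kwargs = dict(
        center=(1800.0, 1800.0),
        initial_radius=500.0,
        area_slope_per_phase=[((45, 60), 3.0e4), ((60, 80), 2.0e5)],
        session_days=[50, 54, 58, 62, 66],
        pixel_size=14.5,
        fov_shape=(248, 248),
        margin_jitter_sd=20.0,
    )
    kwargs.update(overrides)
    return TumorGrowthSpec(**kwargs)
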