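import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vesica import ThicknessLaw
from vesica.measure import measure_phantom
from vesica.phantom import SpeckleModel, geometry_for_volume, render

settings.register_profile(
    "vesica",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vesica")

SPACING = 0.02  # mm / pixel


@pytest.fixture(scope="session")
def law():
    return ThicknessLaw()


@pytest.fixture(scope="session")
def clean_phantom(law):
    """Noiseless spherical phantom at V = 2.0 mL under the default law."""
    truth = geometry_for_volume(2.0, law.ventral_thickness(2.0), law.dorsal_thickness(2.0))
    return render(truth, speckle=SpeckleModel(enabled=False))


@pytest.fixture(scope="session")
def speckle_phantom(law):
    """Default-speckle phantom at V = 2.0 mL, fixed seed."""
    truth = geometry_for_volume(2.0, law.ventral_thickness(2.0), law.dorsal_thickness(2.0))
    return render(truth, seed=1234)


@pytest.fixture(scope="session")
def clean_measurement(clean_phantom):
    return measure_phantom(clean_phantom, smooth_sigma_px=0)


def brute_force_mannwhitney(x, y):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating all
    C(n1+n2, n1) assignments of the pooled tie-free values to the groups."""
    from itertools import combinations

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    idx = range(pooled.size)

    def u_of(subset):
        xs = pooled[list(subset)]
        ys = np.delete(pooled, list(subset))
        return sum((xi > ys).sum() for xi in xs)

    u_obs = sum((xi > y).sum() for xi in x)
    us = np.array([u_of(s) for s in combinations(idx, n1)], dtype=float)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))
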