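import numpy as np
import pytest

from sporemorph.simulate import SporeParams, render_polygon


@pytest.fixture
def capsule_params():
    """A plain spore: straight capsule with an apiculus at the proximal end."""
    return SporeParams(length_um=10.0, width_um=4.0, taper_p=0.5, apiculus_h=0.3)


@pytest.fixture
def capsule(capsule_params):
    return render_polygon(capsule_params, 300)


@pytest.fixture
def bowed_capsule():
    return render_polygon(
        SporeParams(10.0, 4.0, bow_kappa1=0.1, taper_p=0.5, apiculus_h=0.3), 300
    )


def random_outline(rng, n_vertices=None):
    """A random smooth star-shaped polygon (no self-intersections)."""
    m = int(rng.integers(20, 60)) if n_vertices is None else n_vertices
    ang = np.sort(rng.uniform(0, 2 * np.pi, m))
    rad = 1.0 + 0.3 * np.sin(3 * ang + rng.uniform(0, 2 * np.pi)) + rng.normal(0, 0.03, m)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]) * rng.uniform(1, 10)
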