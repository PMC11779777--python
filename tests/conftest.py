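import numpy as np
import pytest

from graphotrace import shapes


@pytest.fixture(scope="session")
def shape_set():
    """The default 8-shape equidistant ring, generated once per session."""
    return shapes.generate_shape_set(seed=1)


@pytest.fixture()
def circle_shape():
    """Unit-radius circle sampled at 512 points, without caliper rescaling."""
    theta = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    return shapes.ContourShape(pts, shape_id=0)


def polar_contour(radius_fn, n=512, shape_id=0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius_fn(theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return shapes.ContourShape(pts, shape_id=shape_id)
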