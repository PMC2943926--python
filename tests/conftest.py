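import numpy as np
import pytest

from gryllomorph import Configuration, Polyline


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def unit_square():
    return Polyline(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), closed=True
    )


def random_configuration(rng, k=8, spread=1.0):
    return Configuration(rng.normal(scale=spread, size=(k, 2)))


def apply_similarity(points, angle, scale, shift):
    rot = np.array(
        [[np.cos(angle), np.sin(angle)], [-np.sin(angle), np.cos(angle)]]
    )
    return scale * (points @ rot) + np.asarray(shift)


def brute_force_min_distance(a, b, step=1e-4):
    """Minimum root-sum-of-squares over a dense rotation grid (no reflection).

    Independent oracle for align_pair: evaluates ||X - Y R(theta)||_F on a
    uniform grid of rotation angles.  For unit preshapes the squared distance
    is 2 - 2*(A cos t + B sin t) with A, B fixed inner products, so the grid
    can be evaluated in closed form.
    """
    from gryllomorph import preshape

    x = preshape(a)
    y = preshape(b)
    t = np.arange(0.0, 2 * np.pi, step)
    # R(t) applied as y @ R: inner product <x, y R(t)> = A cos t + B sin t
    aa = float(np.sum(x * y))
    bb = float(np.sum(x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0]))
    inner = aa * np.cos(t) + bb * np.sin(t)
    d2 = 2.0 - 2.0 * inner
    return float(np.sqrt(max(d2.min(), 0.0)))
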