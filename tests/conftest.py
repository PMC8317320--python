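import numpy as np
import pytest

from rmelm import LongitudinalDesign, ModelState


@pytest.fixture
def rng():
    return np.random.default_rng(20260131)


def random_instance(rng, n=6, p=3, q=1, sizes=None, lam=0.7, Q_scale=0.8):
    """A small random design + interior random state (helper, not a fixture)."""
    if sizes is None:
        sizes = rng.integers(1, 4, size=n)
    subj = np.repeat(np.arange(n), sizes)
    N = subj.shape[0]
    X = rng.standard_normal((N, p))
    Z = np.ones((N, q)) if q == 1 else rng.standard_normal((N, q))
    y = rng.integers(0, 2, size=N).astype(float)
    design = LongitudinalDesign.from_arrays(subj, y, X, Z)
    A = rng.standard_normal((q, q))
    Q = Q_scale * (A @ A.T + np.eye(q))
    state = ModelState(
        beta=rng.standard_normal(p),
        b=0.5 * rng.standard_normal((design.n, q)),
        Q=Q,
        lam=lam,
    )
    return design, state


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)


@pytest.fixture
def three_subject_instance(rng):
    return random_instance(rng, n=3, p=2, q=2, sizes=np.array([2, 3, 2]))


def numeric_gradient(f, x, h=1e-6):
    g = np.zeros_like(x)
    for k in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        g[k] = (f(xp) - f(xm)) / (2 * h)
    return g
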