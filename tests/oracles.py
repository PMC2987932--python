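"""Independent numerical oracles used by the tests.

These deliberately avoid the closed-form solves in the package: line-line
and point-line distances are minimised by dense grid search refined with an
iterative optimiser, and rigid motions are drawn via quaternions. They are
slower but answer the same questions by a different route.
"""
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.transform import Rotation


def brute_min_distance(L1, L2, span=60.0, n=121):
    """Minimal distance between two lines by grid search + BFGS refinement."""
    d1 = L1.direction / np.linalg.norm(L1.direction)
    d2 = L2.direction / np.linalg.norm(L2.direction)
    t = np.linspace(-span, span, n)
    P = L1.p1[None, :] + t[:, None] * d1[None, :]
    Q = L2.p1[None, :] + t[:, None] * d2[None, :]
    d2grid = ((P[:, None, :] - Q[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(d2grid), d2grid.shape)

    def f(x):
        diff = (L1.p1 + x[0] * d1) - (L2.p1 + x[1] * d2)
        return float(diff @ diff)

    res = minimize(f, x0=[t[i], t[j]], method="BFGS", tol=1e-14)
    return float(np.sqrt(max(res.fun, 0.0)))


def brute_closest_point(L, q, span=60.0, n=241):
    """Foot of the perpendicular by grid search + golden-section refinement."""
    d = L.direction / np.linalg.norm(L.direction)
    t = np.linspace(-span, span, n)
    P = L.p1[None, :] + t[:, None] * d[None, :]
    k = int(np.argmin(((P - q[None, :]) ** 2).sum(-1)))
    lo = t[max(k - 1, 0)]
    hi = t[min(k + 1, n - 1)]

    def f(x):
        diff = L.p1 + x * d - q
        return float(diff @ diff)

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return L.p1 + float(res.x) * d


def random_rigid_motion(rng):
    """A uniformly random rotation plus a bounded translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-10, 10, size=3)
    M = R.as_matrix()
    return lambda p: M @ np.asarray(p, dtype=float) + t
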