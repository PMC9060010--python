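import math

import numpy as np
import pytest

from fibremorph.phantoms import CircularArc, Segment, TubeSpec, rasterize_tube


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube r=3 µm, L=50 µm on a 1 µm isotropic grid."""
    spec = TubeSpec(Segment((5, 10, 10), (55, 10, 10)), 3.0)
    mask, truth = rasterize_tube(spec, (20, 20, 62), (1.0, 1.0, 1.0))
    return mask, truth


@pytest.fixture(scope="session")
def quarter_arc_tube():
    """Quarter circular arc R=20 µm, r=3 µm."""
    arc = CircularArc(centre=(10, 15, 10), radius=20.0, span=math.pi / 2)
    mask, truth = rasterize_tube(TubeSpec(arc, 3.0), (20, 45, 40), (1.0, 1.0, 1.0))
    return mask, truth, arc


def circle_points(radius: float, step: float, n: int | None = None) -> np.ndarray:
    """Exact points on a circle in the x-y plane at fixed arc-length step."""
    if n is None:
        n = int(round(2 * math.pi * radius / step)) + 1
    s = np.arange(n) * step
    th = s / radius
    return np.stack(
        [radius * np.cos(th), radius * np.sin(th), np.zeros(n)], axis=1
    )


def brute_force_mwu(a, b, alternative="two-sided"):
    """Independent oracle: U from pairwise comparisons, p by enumerating
    every assignment of the pooled values to groups."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n_a, n_b = len(a), len(b)

    def u_of(xs, ys):
        u = 0.0
        for x in xs:
            for y in ys:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    mu = n_a * n_b / 2.0
    count, total = 0, 0
    for idx in combinations(range(n_a + n_b), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n_a + n_b) if i not in idx]
        u = u_of(ga, gb)
        total += 1
        if alternative == "two-sided":
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            count += u >= u_obs - 1e-12
        else:
            count += u <= u_obs + 1e-12
    return u_obs, count / total
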