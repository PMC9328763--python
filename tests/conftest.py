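import numpy as np
import pytest

from replidyn import Fiber


def assert_intervals_equal(got, want, tol=1e-9):
    got, want = list(got), list(want)
    assert len(got) == len(want), (got, want)
    for (a, b), (c, d) in zip(got, want):
        assert abs(a - c) <= tol and abs(b - d) <= tol, (got, want)


@pytest.fixture
def fiber_a() -> Fiber:
    """100-kb fiber with a sub-threshold gap and a sub-threshold end tract."""
    return Fiber(
        "A", "mock", 60.0, 100.0, [(10, 12), (12.5, 13.2), (40, 45), (99.5, 100)]
    )


@pytest.fixture
def fiber_b() -> Fiber:
    """50-kb fiber with one terminal track and one interior eye."""
    return Fiber("B", "mock", 60.0, 50.0, [(0, 8), (20, 24)])


def random_fiber(rng: np.random.Generator, fiber_id: str = "r") -> Fiber:
    """A random small fiber (<= 10 tracts) exercising every scoring rule."""
    length = rng.uniform(20.0, 120.0)
    n = rng.integers(0, 11)
    cuts = np.sort(rng.uniform(0.0, length, size=2 * n))
    tracts = []
    for a, b in zip(cuts[0::2], cuts[1::2]):
        # snap some tract ends onto the fiber extremities to make terminal
        # tracks and sub-kb gaps common
        if rng.random() < 0.15:
            a = 0.0
        if rng.random() < 0.15:
            b = length
        if b - a > 1e-9:
            tracts.append((float(a), float(b)))
    merged = []
    for a, b in sorted(tracts):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return Fiber(fiber_id, "mock", 30.0, float(length), merged)
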