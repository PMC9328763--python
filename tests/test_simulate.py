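"""Simulator geometry, licensing statistics, determinism and KJMA forms."""

import math

import numpy as np
import pytest

from replidyn import (
    Fiber,
    SimulationParams,
    kjma_fork_density,
    kjma_fraction,
    place_origins,
    replicate_from_events,
    simulate_experiment,
    simulate_fiber,
)
from replidyn.combing import aggregate
from replidyn.simulate import raw_fork_count

from conftest import assert_intervals_equal
from oracles import event_driven_replicate


def test_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(lic_spacing_kb=0)
    with pytest.raises(ValueError):
        SimulationParams(suppression_mock=0.5, suppression_depleted=0.2)
    with pytest.raises(ValueError):
        SimulationParams(sample_times_min=(20.0, 10.0))
    with pytest.raises(ValueError):
        SimulationParams(late_cluster_fraction=1.5)


@pytest.mark.parametrize(
    "events, v, t, L, expected",
    [
        ([(50.0, 10.0)], 0.5, 20.0, 100.0, [(45.0, 55.0)]),
        ([(40.0, 0.0), (50.0, 10.0)], 0.5, 20.0, 100.0, [(30.0, 55.0)]),
        ([], 1.0, 10.0, 100.0, []),
        ([(1.0, 0.0)], 1.0, 5.0, 100.0, [(0.0, 6.0)]),  # clipped at left end
    ],
)
def test_replicate_from_events_geometry(events, v, t, L, expected):
    assert_intervals_equal(replicate_from_events(events, v, t, L), expected)


def test_replicate_monotone_in_time():
    rng = np.random.default_rng(7)
    events = [(float(x), float(tf)) for x, tf in zip(rng.uniform(0, 100, 20), rng.exponential(20, 20))]
    prev = []
    for t in [0, 5, 10, 20, 40, 80]:
        cur = replicate_from_events(events, 0.5, t, 100.0)
        # every earlier tract is contained in some later tract
        for a, b in prev:
            assert any(ca <= a and b <= cb for ca, cb in cur)
        prev = cur


def test_union_geometry_matches_event_driven_oracle():
    """Union-of-grown-intervals equals explicit passive-origin simulation."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = rng.integers(1, 12)
        events = list(zip(rng.uniform(0, 60, n), rng.exponential(15, n)))
        t = float(rng.uniform(0, 40))
        got = replicate_from_events(events, 0.5, t, 60.0)
        want = event_driven_replicate(events, 0.5, t, 60.0)
        assert len(got) == len(want)
        for (a, b), (c, d) in zip(got, want):
            assert a == pytest.approx(c) and b == pytest.approx(d)


def test_place_origins_poisson_mean():
    params = SimulationParams(lic_spacing_kb=3.0)
    rng = np.random.default_rng(123)
    counts = [len(place_origins(300.0, params, rng)) for _ in range(10_000)]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / math.sqrt(len(counts))
    assert abs(mean - 100.0) < 3 * se


def test_place_origins_edge_cases():
    params = SimulationParams(late_cluster_fraction=0.0)
    rng = np.random.default_rng(0)
    assert place_origins(0.001, params, rng) == []  # vanishing interval
    evs = place_origins(500.0, params, rng)
    assert all(e.cluster_class == "early" for e in evs)
    assert all(a.position_kb < b.position_kb for a, b in zip(evs, evs[1:]))
    params_late = SimulationParams(late_cluster_fraction=1.0)
    assert all(
        e.cluster_class == "late" for e in place_origins(500.0, params_late, rng)
    )
    with pytest.raises(ValueError):
        place_origins(-1.0, params, rng)


def test_late_fraction_partitions_length():
    """~half the licensed origins sit in late domains at late fraction 0.5."""
    params = SimulationParams(late_cluster_fraction=0.5, cluster_mean_length_kb=50.0)
    rng = np.random.default_rng(5)
    n_late = n_tot = 0
    for _ in range(200):
        evs = place_origins(1000.0, params, rng)
        n_late += sum(e.cluster_class == "late" for e in evs)
        n_tot += len(evs)
    assert 0.45 < n_late / n_tot < 0.55


def test_simulate_fiber_determinism_and_suppression():
    params = SimulationParams(
        late_cluster_fraction=1.0, suppression_mock=0.0, suppression_depleted=1.0
    )
    f1 = simulate_fiber(params, "mock", 30.0, np.random.default_rng(42), "f")
    f2 = simulate_fiber(params, "mock", 30.0, np.random.default_rng(42), "f")
    assert f1.tracts == f2.tracts
    assert f1.tracts == ()  # all firing suppressed in mock


def test_simulate_fiber_saturation():
    params = SimulationParams(late_cluster_fraction=0.0)
    fib = simulate_fiber(params, "mock", 2000.0, np.random.default_rng(3))
    assert fib.replicated_kb / fib.length_kb > 0.999


def test_label_start_excludes_prelabel_synthesis():
    base = SimulationParams(late_cluster_fraction=0.0, seed=9)
    labelled = SimulationParams(late_cluster_fraction=0.0, seed=9, label_start_min=10.0)
    full = simulate_fiber(base, "mock", 30.0, np.random.default_rng(9))
    part = simulate_fiber(labelled, "mock", 30.0, np.random.default_rng(9))
    assert part.replicated_kb <= full.replicated_kb
    # labelled tracts lie inside the fully replicated region
    for a, b in part.tracts:
        assert any(ca <= a and b <= cb for ca, cb in full.tracts)


def test_simulate_experiment_counts_and_reproducibility():
    params = SimulationParams(n_fibers=10, sample_times_min=(10.0, 20.0))
    fibers, manifest = simulate_experiment(params)
    assert len(fibers) == 40  # 10 fibers x 2 conditions x 2 times
    assert manifest["params"]["n_fibers"] == 10
    fibers2, _ = simulate_experiment(params)
    assert [f.tracts for f in fibers] == [f.tracts for f in fibers2]


def test_exchangeable_conditions_give_unit_ratio():
    """s_mock = s_dep makes mock and depleted statistically exchangeable."""
    ratios = []
    for seed in range(15):
        params = SimulationParams(
            n_fibers=60,
            suppression_mock=0.5,
            suppression_depleted=0.5,
            sample_times_min=(20.0,),
            seed=seed,
        )
        fibers, _ = simulate_experiment(params)
        by_cond = {
            c: aggregate([f for f in fibers if f.condition == c])
            for c in ("mock", "depleted")
        }
        ratios.append(
            by_cond["depleted"].fork_density_per_100kb
            / by_cond["mock"].fork_density_per_100kb
        )
    mean = np.mean(ratios)
    se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
    assert abs(mean - 1.0) < 3 * se


@pytest.mark.parametrize(
    "fn, expected",
    [
        (lambda: kjma_fraction(0.001, 0.5, 20.0), 1 - math.exp(-0.2)),
        (lambda: kjma_fraction(0.001, 0.5, 0.0), 0.0),
        (lambda: kjma_fraction(0.0, 0.5, 50.0), 0.0),
        (lambda: kjma_fork_density(0.001, 0.5, 20.0), 0.04 * math.exp(-0.2)),
        (lambda: kjma_fork_density(0.001, 0.5, 0.0), 0.0),
    ],
)
def test_kjma_closed_forms(fn, expected):
    assert fn() == pytest.approx(expected, rel=1e-12)


def test_kjma_errors_and_fork_density_peak():
    with pytest.raises(ValueError):
        kjma_fraction(-0.001, 0.5, 10.0)
    with pytest.raises(ValueError):
        kjma_fork_density(0.001, -0.5, 10.0)
    I, v = 0.002, 0.4
    t_star = 1.0 / math.sqrt(2 * I * v)
    ts = np.linspace(0.1, 3 * t_star, 2000)
    dens = [kjma_fork_density(I, v, t) for t in ts]
    assert ts[int(np.argmax(dens))] == pytest.approx(t_star, rel=0.01)


def test_raw_fork_count_excludes_fiber_ends():
    fib = Fiber("f", "mock", 10.0, 100.0, [(0, 5), (40, 45), (98, 100)])
    assert raw_fork_count(fib) == 4  # boundary tracts lose their outer fork
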