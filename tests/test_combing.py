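"""Combing calculus: scoring rules, pooling, table IO, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replidyn import (
    AnalysisConfig,
    Fiber,
    aggregate,
    call_eyes,
    fiber_summary,
    merge_gaps,
    read_fiber_table,
)
from replidyn.combing import write_eye_bed
from replidyn.simulate import SimulationParams, simulate_experiment, write_fiber_table

from conftest import assert_intervals_equal, random_fiber
from oracles import brute_fiber_summary


@pytest.mark.parametrize(
    "tracts, min_gap, expected",
    [
        ([(10, 12), (12.5, 13.2)], 1.0, [(10, 13.2)]),  # 0.5 kb is not a gap
        ([(10, 12), (13.5, 14.5)], 1.0, [(10, 12), (13.5, 14.5)]),  # 1.5 kb is
        ([(10, 12), (13.0, 14.0)], 1.0, [(10, 12), (13.0, 14.0)]),  # exactly 1 kb kept
        ([], 1.0, []),
    ],
)
def test_merge_gaps(tracts, min_gap, expected):
    assert_intervals_equal(merge_gaps(tracts, min_gap), expected)


def test_merge_gaps_idempotent_and_validating():
    out = merge_gaps([(0, 1), (1.2, 2), (5, 6)], 1.0)
    assert merge_gaps(out, 1.0) == out
    with pytest.raises(ValueError):
        merge_gaps([(5, 6), (0, 1)], 1.0)  # unsorted
    with pytest.raises(ValueError):
        merge_gaps([(0, 3), (2, 5)], 1.0)  # overlapping


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    cuts=st.lists(
        st.floats(0.001, 99.999, allow_nan=False), unique=True, max_size=20
    ),
    min_gap=st.floats(0.1, 5.0),
)
def test_merge_gaps_properties(cuts, min_gap):
    """Gap-merging is idempotent, keeps all label, and leaves only real gaps."""
    cuts = sorted(cuts)
    tracts = list(zip(cuts[0::2], cuts[1::2]))
    merged = merge_gaps(tracts, min_gap)
    assert merge_gaps(merged, min_gap) == merged
    assert sum(b - a for a, b in merged) >= sum(b - a for a, b in tracts) - 1e-9
    for (_, b1), (a2, _) in zip(merged, merged[1:]):
        assert a2 - b1 >= min_gap - 1e-9


def test_call_eyes_worked_example_a(fiber_a):
    calls = call_eyes(fiber_a)
    assert_intervals_equal(calls.eyes, [(10.0, 13.2), (40.0, 45.0)])
    assert calls.terminal_tracks == ()
    assert_intervals_equal(calls.discarded_tracts, [(99.5, 100.0)])
    assert calls.fork_count == 4


def test_call_eyes_worked_example_b(fiber_b):
    calls = call_eyes(fiber_b)
    assert_intervals_equal(calls.eyes, [(20.0, 24.0)])
    assert_intervals_equal(calls.terminal_tracks, [(0.0, 8.0)])
    assert calls.fork_count == 3


def test_call_eyes_fully_replicated_fiber():
    calls = call_eyes(Fiber("full", "mock", 60, 100.0, [(0, 100)]))
    assert calls.eyes == ()
    assert_intervals_equal(calls.terminal_tracks, [(0.0, 100.0)])
    assert calls.fork_count == 0  # both forks ran off the molecule


def test_fiber_summary_worked_examples(fiber_a, fiber_b):
    sa = fiber_summary(call_eyes(fiber_a))
    assert sa.replicated_kb == pytest.approx(8.2)
    assert sa.eye_lengths_kb == pytest.approx((3.2, 5.0))
    assert sa.origins_kb == pytest.approx((11.6, 42.5))
    assert sa.eteds_kb == pytest.approx((30.9,))
    sb = fiber_summary(call_eyes(fiber_b))
    assert sb.replicated_kb == pytest.approx(12.0)
    assert sb.eye_lengths_kb == pytest.approx((4.0,))
    assert sb.eteds_kb == ()
    empty = fiber_summary(call_eyes(Fiber("e", "mock", 60, 30.0, [])))
    assert empty.replicated_kb == 0 and empty.n_eyes == 0


def test_aggregate_pooled_worked_example(fiber_a, fiber_b):
    stats = aggregate([fiber_a, fiber_b])
    assert stats.replicated_fraction == pytest.approx(20.2 / 150)
    assert stats.fork_density_per_100kb == pytest.approx(100 * 7 / 150)
    assert stats.pct_unreplicated_fibers == 0.0


def test_aggregate_edge_cases(fiber_a, fiber_b):
    only_empty = aggregate([Fiber("e", "mock", 60, 30.0, [])])
    assert only_empty.replicated_fraction == 0.0
    assert only_empty.fork_density_per_100kb == 0.0
    assert only_empty.pct_unreplicated_fibers == 100.0
    once = aggregate([fiber_a, fiber_b])
    twice = aggregate(
        [fiber_a, fiber_b]
        + [
            Fiber("A2", "mock", 60, fiber_a.length_kb, fiber_a.tracts),
            Fiber("B2", "mock", 60, fiber_b.length_kb, fiber_b.tracts),
        ]
    )
    assert twice.replicated_fraction == pytest.approx(once.replicated_fraction)
    assert twice.fork_density_per_100kb == pytest.approx(once.fork_density_per_100kb)
    with pytest.raises(ValueError):
        aggregate([])
    with pytest.raises(ValueError):
        aggregate([fiber_a, Fiber("C", "depleted", 60, 10.0, [])])


def test_calculus_matches_bruteforce_oracle():
    """Random small fibers agree exactly with the literal-rules oracle."""
    rng = np.random.default_rng(2024)
    cfg = AnalysisConfig()
    for i in range(1000):
        fib = random_fiber(rng, f"r{i}")
        got = fiber_summary(call_eyes(fib, cfg))
        want = brute_fiber_summary(fib.length_kb, fib.tracts)
        assert got.fork_count == want["fork_count"], fib
        assert got.n_eyes == want["n_eyes"], fib
        assert got.replicated_kb == pytest.approx(want["replicated_kb"])
        assert list(got.eye_lengths_kb) == pytest.approx(want["eye_lengths_kb"])
        assert list(got.eteds_kb) == pytest.approx(want["eteds_kb"])
        assert list(got.origins_kb) == pytest.approx(want["origins_kb"])


def test_lowering_eye_threshold_never_decreases_forks():
    """A smaller min_eye_kb only rescues discarded tracts, never loses forks.

    (The analogous claim for min_gap_kb is false: splitting a merged eye can
    leave sub-threshold fragments that the size filter then discards.)
    """
    rng = np.random.default_rng(77)
    for i in range(300):
        fib = random_fiber(rng, f"t{i}")
        loose = call_eyes(fib, AnalysisConfig(min_eye_kb=0.5))
        strict = call_eyes(fib, AnalysisConfig(min_eye_kb=1.5))
        assert loose.fork_count >= strict.fork_count
        summ = fiber_summary(loose)
        assert sum(summ.eye_lengths_kb) <= summ.replicated_kb <= fib.length_kb


def test_fiber_table_round_trip(tmp_path):
    params = SimulationParams(n_fibers=15, sample_times_min=(10.0, 25.0), seed=4)
    fibers, _ = simulate_experiment(params)
    path = tmp_path / "fibers.tsv"
    write_fiber_table(fibers, path)
    text = path.read_text()
    back = read_fiber_table(path)
    assert len(back) == len(fibers)
    path2 = tmp_path / "again.tsv"
    write_fiber_table(back, path2)
    assert path2.read_text() == text  # write(read(x)) == x
    # unreplicated fibers keep their empty-tract row and count in totals
    n_empty = sum(1 for f in fibers if not f.tracts)
    assert sum(1 for f in back if not f.tracts) == n_empty


def test_fiber_table_rejects_malformed_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    header = (
        "condition\ttime_min\tfiber_id\tfiber_length_kb\t"
        "tract_start_kb\ttract_end_kb\n"
    )
    path.write_text(header + "mock\t10\tfibX\t100.000\t5.000\t2.000\n")
    with pytest.raises(ValueError, match="fibX"):
        read_fiber_table(path)
    path.write_text(
        header
        + "mock\t10\tfibY\t100.000\t1.000\t4.000\n"
        + "mock\t10\tfibY\t100.000\t3.000\t6.000\n"
    )
    with pytest.raises(ValueError, match="fibY"):
        read_fiber_table(path)
    path.write_text(header + "mock\t10\tfibZ\t100.000\t50.000\t120.000\n")
    with pytest.raises(ValueError, match="fibZ"):
        read_fiber_table(path)


def test_eye_bed_export(tmp_path, fiber_a):
    path = tmp_path / "eyes.bed"
    write_eye_bed([call_eyes(fiber_a)], path)
    assert path.read_text() == "A\t10000\t13200\nA\t40000\t45000\n"
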