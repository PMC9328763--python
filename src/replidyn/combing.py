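"""DNA-combing measurement calculus.

Turns labelled tracts on single combed fibers into the standard combing
readouts: replication eyes, fork counts, replicated fraction, fork density,
eye lengths (EL), eye-to-eye distances (ETED) and origin positions.

Scoring rules, in order:

1. sub-threshold *gaps* between labelled tracts (< ``min_gap_kb``) are not
   real gaps — the flanking tracts are merged;
2. surviving tracts shorter than ``min_eye_kb`` are detection noise and are
   discarded from every count;
3. a tract touching one fiber extremity is a *terminal track* — the product
   of a single fork (its partner ran off the molecule); a tract spanning
   both extremities carries no on-fiber fork; every interior tract is a
   replication *eye*, the product of two diverging forks.

Eyes define origins (their midpoints) and ETEDs (midpoint-to-midpoint
distances between adjacent eyes). Terminal tracks count toward replicated
length but are not eyes, so they contribute neither EL nor origins.
Aggregation is pooled (length-weighted): replicated fraction is the summed
labelled length over the summed fiber length, and fork density is forks per
``density_window_kb`` (100 kb by default) of total DNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .simulate import Fiber

__all__ = [
    "AnalysisConfig",
    "EyeCalls",
    "FiberSummary",
    "CombingStats",
    "merge_gaps",
    "call_eyes",
    "fiber_summary",
    "aggregate",
    "read_fiber_table",
    "write_fiber_summaries",
    "write_combing_stats",
    "write_eye_bed",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the combing calculus (all kb, all >= 0)."""

    min_eye_kb: float = 1.0
    min_gap_kb: float = 1.0
    terminal_tolerance_kb: float = 0.0
    density_window_kb: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "min_eye_kb",
            "min_gap_kb",
            "terminal_tolerance_kb",
            "density_window_kb",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EyeCalls:
    fiber: Fiber
    eyes: tuple[Interval, ...]
    terminal_tracks: tuple[Interval, ...]
    fork_count: int
    discarded_tracts: tuple[Interval, ...]


@dataclass(frozen=True)
class FiberSummary:
    fiber_id: str
    length_kb: float
    replicated_kb: float
    n_eyes: int
    eye_lengths_kb: tuple[float, ...]
    eteds_kb: tuple[float, ...]
    origins_kb: tuple[float, ...]
    fork_count: int


@dataclass(frozen=True)
class CombingStats:
    condition: str
    time_min: float
    n_fibers: int
    total_dna_kb: float
    replicated_fraction: float
    fork_density_per_100kb: float
    eye_lengths_kb: tuple[float, ...]
    eteds_kb: tuple[float, ...]
    pct_unreplicated_fibers: float


def _check_sorted_disjoint(tracts: Sequence[Interval]) -> None:
    for a, b in tracts:
        if b <= a:
            raise ValueError(f"empty or inverted tract [{a}, {b})")
    for (a1, b1), (a2, b2) in zip(tracts, tracts[1:]):
        if a2 < b1:
            raise ValueError(
                f"tracts [{a1}, {b1}) and [{a2}, {b2}) are unsorted or overlap"
            )


def merge_gaps(tracts: Sequence[Interval], min_gap_kb: float) -> list[Interval]:
    """Merge labelled tracts across gaps shorter than ``min_gap_kb``.

    A gap of exactly ``min_gap_kb`` is a real gap and is kept. Idempotent;
    total labelled length never decreases.
    """
    _check_sorted_disjoint(tracts)
    out: list[list[float]] = []
    for a, b in tracts:
        if out and a - out[-1][1] < min_gap_kb:
            out[-1][1] = b
        else:
            out.append([float(a), float(b)])
    return [(a, b) for a, b in out]


def call_eyes(fiber: Fiber, config: AnalysisConfig = AnalysisConfig()) -> EyeCalls:
    """Score a fiber's tracts into eyes and terminal tracks.

    Gap-merging runs first (merging defines the tract before it is scored),
    then the ``min_eye_kb`` size filter — applied to terminal tracts too —
    then terminal classification within ``terminal_tolerance_kb`` of either
    fiber end.
    """
    merged = merge_gaps(fiber.tracts, config.min_gap_kb)
    eyes: list[Interval] = []
    terminal: list[Interval] = []
    discarded: list[Interval] = []
    forks = 0
    tol = config.terminal_tolerance_kb
    for a, b in merged:
        if b - a < config.min_eye_kb:
            discarded.append((a, b))
            continue
        at_start = a <= tol
        at_end = b >= fiber.length_kb - tol
        if at_start and at_end:
            terminal.append((a, b))  # both forks ran off the molecule
        elif at_start or at_end:
            terminal.append((a, b))
            forks += 1
        else:
            eyes.append((a, b))
            forks += 2
    return EyeCalls(
        fiber=fiber,
        eyes=tuple(eyes),
        terminal_tracks=tuple(terminal),
        fork_count=forks,
        discarded_tracts=tuple(discarded),
    )


def fiber_summary(calls: EyeCalls) -> FiberSummary:
    """Per-fiber EL/ETED/origin summary from scored eye calls."""
    eyes = calls.eyes
    replicated = sum(b - a for a, b in eyes) + sum(
        b - a for a, b in calls.terminal_tracks
    )
    midpoints = tuple((a + b) / 2.0 for a, b in eyes)
    eteds = tuple(m2 - m1 for m1, m2 in zip(midpoints, midpoints[1:]))
    return FiberSummary(
        fiber_id=calls.fiber.fiber_id,
        length_kb=calls.fiber.length_kb,
        replicated_kb=replicated,
        n_eyes=len(eyes),
        eye_lengths_kb=tuple(b - a for a, b in eyes),
        eteds_kb=eteds,
        origins_kb=midpoints,
        fork_count=calls.fork_count,
    )


def aggregate(
    fibers: Sequence[Fiber],
    config: AnalysisConfig = AnalysisConfig(),
    condition: str | None = None,
    time_min: float | None = None,
) -> CombingStats:
    """Pool fibers of one condition/time into length-weighted statistics.

    Pooled, not per-fiber-averaged: replicated fraction is total labelled kb
    over total kb, fork density is ``density_window_kb * forks / total kb``.
    """
    if not fibers:
        raise ValueError("aggregate requires at least one fiber")
    cond = condition if condition is not None else fibers[0].condition
    t = float(time_min) if time_min is not None else fibers[0].time_min
    for f in fibers:
        if f.condition != cond or f.time_min != t:
            raise ValueError(
                f"fiber {f.fiber_id} is {f.condition}@{f.time_min}, expected {cond}@{t}"
            )
    summaries = [fiber_summary(call_eyes(f, config)) for f in fibers]
    total = sum(s.length_kb for s in summaries)
    repl = sum(s.replicated_kb for s in summaries)
    forks = sum(s.fork_count for s in summaries)
    els: list[float] = []
    eteds: list[float] = []
    for s in summaries:
        els.extend(s.eye_lengths_kb)
        eteds.extend(s.eteds_kb)
    n_unrep = sum(1 for s in summaries if s.replicated_kb == 0)
    return CombingStats(
        condition=cond,
        time_min=t,
        n_fibers=len(summaries),
        total_dna_kb=total,
        replicated_fraction=repl / total,
        fork_density_per_100kb=config.density_window_kb * forks / total,
        eye_lengths_kb=tuple(els),
        eteds_kb=tuple(eteds),
        pct_unreplicated_fibers=100.0 * n_unrep / len(summaries),
    )


# ---------------------------------------------------------------------------
# table IO

_HEADER = [
    "condition",
    "time_min",
    "fiber_id",
    "fiber_length_kb",
    "tract_start_kb",
    "tract_end_kb",
]


def read_fiber_table(path) -> list[Fiber]:
    """Read the fiber tract TSV; malformed rows raise with line numbers.

    Rows sharing (condition, time_min, fiber_id) belong to one fiber; an
    empty tract pair means an unreplicated fiber (still counted in totals).
    """
    fibers: dict[tuple[str, float, str], dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            cond, t_s, fid, len_s, a_s, b_s = parts
            try:
                t = float(t_s)
                length = float(len_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric field: {exc}") from None
            key = (cond, t, fid)
            rec = fibers.setdefault(key, {"length": length, "tracts": []})
            if rec["length"] != length:
                raise ValueError(
                    f"{path}:{lineno}: fiber {fid!r} has inconsistent lengths"
                )
            if a_s == "" and b_s == "":
                continue
            try:
                a, b = float(a_s), float(b_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad tract field: {exc}") from None
            if b <= a:
                raise ValueError(
                    f"{path}:{lineno}: fiber {fid!r} tract end {b} <= start {a}"
                )
            if a < 0 or b > length:
                raise ValueError(
                    f"{path}:{lineno}: fiber {fid!r} tract [{a}, {b}) outside [0, {length})"
                )
            rec["tracts"].append((a, b))
    out: list[Fiber] = []
    for (cond, t, fid), rec in fibers.items():
        tracts = sorted(rec["tracts"])
        for (a1, b1), (a2, b2) in zip(tracts, tracts[1:]):
            if a2 < b1:
                raise ValueError(
                    f"{path}: fiber {fid!r} has overlapping tracts "
                    f"[{a1}, {b1}) and [{a2}, {b2})"
                )
        out.append(
            Fiber(fiber_id=fid, condition=cond, time_min=t, length_kb=rec["length"], tracts=tuple(tracts))
        )
    return out


def write_fiber_summaries(summaries: Iterable[FiberSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "fiber_id\tlength_kb\treplicated_kb\tn_eyes\tfork_count\t"
            "eye_lengths_kb\teteds_kb\torigins_kb\n"
        )
        for s in summaries:
            fh.write(
                f"{s.fiber_id}\t{s.length_kb:.3f}\t{s.replicated_kb:.3f}\t"
                f"{s.n_eyes}\t{s.fork_count}\t"
                f"{','.join(f'{x:.3f}' for x in s.eye_lengths_kb)}\t"
                f"{','.join(f'{x:.3f}' for x in s.eteds_kb)}\t"
                f"{','.join(f'{x:.3f}' for x in s.origins_kb)}\n"
            )


def write_combing_stats(stats: Iterable[CombingStats], tsv_path, json_path=None) -> None:
    stats = list(stats)
    with open(tsv_path, "w") as fh:
        fh.write(
            "condition\ttime_min\tn_fibers\ttotal_dna_kb\treplicated_fraction\t"
            "fork_density_per_100kb\tpct_unreplicated_fibers\tn_eyes\tn_eteds\n"
        )
        for s in stats:
            fh.write(
                f"{s.condition}\t{s.time_min:g}\t{s.n_fibers}\t{s.total_dna_kb:.3f}\t"
                f"{s.replicated_fraction:.6f}\t{s.fork_density_per_100kb:.6f}\t"
                f"{s.pct_unreplicated_fibers:.3f}\t{len(s.eye_lengths_kb)}\t"
                f"{len(s.eteds_kb)}\n"
            )
    if json_path is not None:
        payload = [
            {
                "condition": s.condition,
                "time_min": s.time_min,
                "n_fibers": s.n_fibers,
                "total_dna_kb": s.total_dna_kb,
                "replicated_fraction": s.replicated_fraction,
                "fork_density_per_100kb": s.fork_density_per_100kb,
                "pct_unreplicated_fibers": s.pct_unreplicated_fibers,
                "eye_lengths_kb": list(s.eye_lengths_kb),
                "eteds_kb": list(s.eteds_kb),
            }
            for s in stats
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def write_eye_bed(calls: Iterable[EyeCalls], path) -> None:
    """BED3 export of eyes: chrom = fiber_id, coordinates bp = kb*1000."""
    with open(path, "w") as fh:
        for c in calls:
            for a, b in c.eyes:
                fh.write(f"{c.fiber.fiber_id}\t{round(a * 1000)}\t{round(b * 1000)}\n")
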