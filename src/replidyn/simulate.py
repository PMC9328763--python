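"""Stochastic single-fiber DNA replication simulator.

Emulates DNA-combing experiments in *Xenopus* egg extracts: potential
(licensed) origins are laid down as a homogeneous Poisson process along each
fiber, assigned to alternating early/late firing domains, and fired with
exponential waiting times. A depleted condition (loss of a late-origin
repressor such as Yap or Rif1) is modelled purely as a larger firing-rate
multiplier inside late domains. Continuous labelling from the start of
S-phase means every replicated base appears as a labelled tract.

Geometry follows the one-dimensional nucleation-and-growth (KJMA) picture:
each fired origin grows a replication eye bidirectionally at constant fork
speed ``v``; overlapping eyes merge; an origin overrun before its own firing
time is passively replicated and adds nothing. With equal fork speeds the
interval grown from a passively replicated origin is always contained in the
eye that overran it, so the replicated region is exactly the union of the
individually grown intervals — this is what :func:`replicate_from_events`
computes, and why no explicit passive-firing bookkeeping is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SimulationParams",
    "Fiber",
    "FiringEvent",
    "place_origins",
    "replicate_from_events",
    "simulate_fiber",
    "simulate_experiment",
    "kjma_fraction",
    "kjma_fork_density",
    "kjma_validation_run",
    "write_fiber_table",
    "write_manifest",
    "read_manifest",
]

CONDITIONS = ("mock", "depleted")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a mock/depleted combing simulation.

    Defaults emulate early *Xenopus* embryonic S-phase: licensed origins
    every ~3 kb (activated spacing lands in the 5–15 kb range after passive
    replication), fork speed 0.5 kb/min, and an early-origin firing rate
    that spreads origin activation over tens of minutes. Late domains fire
    at ``I0 * suppression`` — 10% of the early rate in mock extracts, fully
    derepressed (100%) after depletion of the late-origin brake.
    """

    n_fibers: int = 100
    fiber_length_kb: float = 100.0
    lic_spacing_kb: float = 3.0
    fork_speed_kb_per_min: float = 0.5
    firing_rate_per_origin_per_min: float = 0.01
    cluster_mean_length_kb: float = 150.0
    late_cluster_fraction: float = 0.5
    suppression_mock: float = 0.1
    suppression_depleted: float = 1.0
    sample_times_min: tuple[float, ...] = (10.0, 20.0, 30.0)
    label_start_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be a positive integer")
        for name in (
            "fiber_length_kb",
            "lic_spacing_kb",
            "fork_speed_kb_per_min",
            "firing_rate_per_origin_per_min",
            "cluster_mean_length_kb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.late_cluster_fraction <= 1.0:
            raise ValueError("late_cluster_fraction must be in [0, 1]")
        for name in ("suppression_mock", "suppression_depleted"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.suppression_mock > self.suppression_depleted:
            raise ValueError(
                "suppression_mock must not exceed suppression_depleted "
                "(depletion derepresses late firing)"
            )
        if self.label_start_min < 0:
            raise ValueError("label_start_min must be >= 0")
        times = tuple(float(t) for t in self.sample_times_min)
        if not times or any(t <= 0 for t in times):
            raise ValueError("sample_times_min must be strictly positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times_min must be strictly increasing")
        object.__setattr__(self, "sample_times_min", times)

    def suppression(self, condition: str) -> float:
        if condition == "mock":
            return self.suppression_mock
        if condition == "depleted":
            return self.suppression_depleted
        raise ValueError(f"unknown condition {condition!r}")

    def to_dict(self) -> dict:
        return {
            "n_fibers": self.n_fibers,
            "fiber_length_kb": self.fiber_length_kb,
            "lic_spacing_kb": self.lic_spacing_kb,
            "fork_speed_kb_per_min": self.fork_speed_kb_per_min,
            "firing_rate_per_origin_per_min": self.firing_rate_per_origin_per_min,
            "cluster_mean_length_kb": self.cluster_mean_length_kb,
            "late_cluster_fraction": self.late_cluster_fraction,
            "suppression_mock": self.suppression_mock,
            "suppression_depleted": self.suppression_depleted,
            "sample_times_min": list(self.sample_times_min),
            "label_start_min": self.label_start_min,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class FiringEvent:
    """A licensed origin: position, (potential) firing time, timing class."""

    position_kb: float
    fire_time_min: float = math.inf  # inf = never fires
    cluster_class: str = "early"

    def __post_init__(self) -> None:
        if self.fire_time_min < 0:
            raise ValueError("fire_time_min must be >= 0")
        if self.cluster_class not in ("early", "late"):
            raise ValueError("cluster_class must be 'early' or 'late'")


def _normalize_tracts(
    tracts: Iterable[tuple[float, float]], length_kb: float
) -> tuple[tuple[float, float], ...]:
    """Sort, bounds-check and merge abutting/overlapping intervals."""
    items = sorted((float(a), float(b)) for a, b in tracts)
    merged: list[list[float]] = []
    for a, b in items:
        if not (0.0 <= a < b <= length_kb + 1e-9):
            raise ValueError(
                f"tract [{a}, {b}) outside fiber bounds [0, {length_kb})"
            )
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, min(b, length_kb)])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class Fiber:
    """One combed DNA molecule: total length plus labelled tracts (kb).

    Tracts are half-open ``[start, end)`` intervals, sorted, disjoint and
    non-abutting (merged on construction).
    """

    fiber_id: str
    condition: str
    time_min: float
    length_kb: float
    tracts: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValueError("length_kb must be strictly positive")
        object.__setattr__(
            self, "tracts", _normalize_tracts(self.tracts, self.length_kb)
        )

    @property
    def replicated_kb(self) -> float:
        return sum(b - a for a, b in self.tracts)


# ---------------------------------------------------------------------------
# origin placement and replication geometry


def place_origins(
    length_kb: float,
    params: SimulationParams,
    rng: np.random.Generator,
    margin_kb: float = 0.0,
) -> list[FiringEvent]:
    """Poisson-license potential origins on ``[-margin, length + margin]``.

    Origins are classed early/late by the alternating timing domain that
    contains them. Domain lengths are exponential; the late-domain mean is
    scaled so the expected proportion of fiber length in late domains equals
    ``late_cluster_fraction`` while the overall mean domain length stays at
    ``cluster_mean_length_kb``.
    """
    if length_kb <= 0:
        raise ValueError("length_kb must be strictly positive")
    lo, hi = -margin_kb, length_kb + margin_kb
    span = hi - lo
    n = rng.poisson(span / params.lic_spacing_kb)
    positions = np.sort(rng.uniform(lo, hi, size=n))

    f = params.late_cluster_fraction
    if f == 0.0:
        classes = ["early"] * n
    elif f == 1.0:
        classes = ["late"] * n
    else:
        mean_late = 2.0 * f * params.cluster_mean_length_kb
        mean_early = 2.0 * (1.0 - f) * params.cluster_mean_length_kb
        # length-biased start phase: P(point falls in a late domain) = f
        current = "late" if rng.random() < f else "early"
        edge = lo
        classes = []
        i = 0
        while i < n:
            edge += rng.exponential(mean_late if current == "late" else mean_early)
            while i < n and positions[i] < edge:
                classes.append(current)
                i += 1
            current = "early" if current == "late" else "late"
    return [
        FiringEvent(position_kb=float(x), cluster_class=c)
        for x, c in zip(positions, classes)
    ]


def replicate_from_events(
    events: Iterable[tuple[float, float]],
    v: float,
    t: float,
    length_kb: float,
) -> list[tuple[float, float]]:
    """Replicated tracts at time ``t`` from (position, fire_time) pairs.

    Each origin fired by ``t`` contributes ``[x - v(t - t_f), x + v(t - t_f)]``
    clipped to ``[0, length_kb]``; the union is returned. Passively
    replicated origins need no special handling (their interval is nested in
    the overrunning eye; see module docstring). Monotone in ``t``.
    """
    if v <= 0:
        raise ValueError("fork speed v must be strictly positive")
    if t < 0:
        raise ValueError("time t must be >= 0")
    ev = [(float(x), float(tf)) for x, tf in events]
    if not ev:
        return []
    xs = np.array([x for x, _ in ev])
    tfs = np.array([tf for _, tf in ev])
    fired = tfs < t
    if not fired.any():
        return []
    half = v * (t - tfs[fired])
    starts = np.clip(xs[fired] - half, 0.0, length_kb)
    ends = np.clip(xs[fired] + half, 0.0, length_kb)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return []
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    merged_s = [starts[0]]
    merged_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            if e > merged_e[-1]:
                merged_e[-1] = e
        else:
            merged_s.append(s)
            merged_e.append(e)
    return [(float(s), float(e)) for s, e in zip(merged_s, merged_e)]


def _subtract_intervals(
    a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Set difference a \\ b for sorted disjoint interval lists."""
    out: list[tuple[float, float]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _draw_fire_times(
    events: list[FiringEvent],
    params: SimulationParams,
    condition: str,
    rng: np.random.Generator,
) -> list[FiringEvent]:
    i0 = params.firing_rate_per_origin_per_min
    s = params.suppression(condition)
    out = []
    for ev in events:
        rate = i0 if ev.cluster_class == "early" else i0 * s
        tf = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        out.append(replace(ev, fire_time_min=tf))
    return out


def simulate_fiber(
    params: SimulationParams,
    condition: str,
    time_min: float,
    rng: np.random.Generator,
    fiber_id: str = "fiber",
    margin_kb: float = 0.0,
) -> Fiber:
    """Simulate one fiber sampled (combed) at ``time_min``.

    ``margin_kb`` extends origin licensing beyond both fiber ends while
    tracts stay clipped to the fiber; a margin of at least ``v * time_min``
    makes the interior statistics those of an unbounded fiber.
    """
    if time_min < 0:
        raise ValueError("time_min must be >= 0")
    events = place_origins(params.fiber_length_kb, params, rng, margin_kb=margin_kb)
    events = _draw_fire_times(events, params, condition, rng)
    pairs = [(ev.position_kb, ev.fire_time_min) for ev in events]
    v = params.fork_speed_kb_per_min
    tracts = replicate_from_events(pairs, v, time_min, params.fiber_length_kb)
    if params.label_start_min > 0:
        # label only DNA synthesised after labelling began
        pre = replicate_from_events(
            pairs, v, min(params.label_start_min, time_min), params.fiber_length_kb
        )
        tracts = _subtract_intervals(tracts, pre)
    return Fiber(
        fiber_id=fiber_id,
        condition=condition,
        time_min=float(time_min),
        length_kb=params.fiber_length_kb,
        tracts=tuple(tracts),
    )


def _fiber_rng(seed: int, cond_idx: int, time_idx: int, fiber_idx: int) -> np.random.Generator:
    # deterministic per-fiber substream: (seed, condition, time, fiber)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cond_idx, time_idx, fiber_idx))
    )


def simulate_experiment(
    params: SimulationParams, margin_kb: float = 0.0
) -> tuple[list[Fiber], dict]:
    """Simulate both conditions at every sample time.

    Returns ``n_fibers`` fibers per condition per time plus a manifest dict
    recording all parameters and the seed. Byte-identical for a given seed.
    """
    fibers: list[Fiber] = []
    for ci, condition in enumerate(CONDITIONS):
        for ti, t in enumerate(params.sample_times_min):
            for i in range(params.n_fibers):
                rng = _fiber_rng(params.seed, ci, ti, i)
                fibers.append(
                    simulate_fiber(
                        params,
                        condition,
                        t,
                        rng,
                        fiber_id=f"{condition}_t{ti}_f{i:05d}",
                        margin_kb=margin_kb,
                    )
                )
    manifest = {"params": params.to_dict(), "seed": params.seed}
    return fibers, manifest


# ---------------------------------------------------------------------------
# closed-form KJMA (nucleation-and-growth) validation helpers


def kjma_fraction(I_kb_min: float, v: float, t: float) -> float:
    """Replicated fraction 1 - exp(-I v t^2) of an unbounded uniform fiber.

    ``I_kb_min`` is the nucleation rate per kb per min, ``v`` the fork speed
    in kb/min. Constant-rate one-dimensional KJMA kinetics.
    """
    if I_kb_min < 0 or v < 0 or t < 0:
        raise ValueError("I, v and t must be >= 0")
    return 1.0 - math.exp(-I_kb_min * v * t * t)


def kjma_fork_density(I_kb_min: float, v: float, t: float) -> float:
    """Active forks per kb, 2 I t exp(-I v t^2), for the same model."""
    if I_kb_min < 0 or v < 0 or t < 0:
        raise ValueError("I, v and t must be >= 0")
    return 2.0 * I_kb_min * t * math.exp(-I_kb_min * v * t * t)


def raw_fork_count(fiber: Fiber) -> int:
    """Number of active forks = tract boundaries strictly inside the fiber."""
    n = 0
    for a, b in fiber.tracts:
        n += int(a > 0.0) + int(b < fiber.length_kb)
    return n


def kjma_validation_run(
    I_kb_min: float,
    v: float,
    times: Sequence[float],
    n_fibers: int = 500,
    fiber_length_kb: float = 1000.0,
    seed: int = 0,
) -> dict[float, dict[str, float]]:
    """Monte-Carlo check of the simulator against the KJMA closed forms.

    Simulates homogeneous fibers (no late clusters, licensing spacing 1 kb,
    per-origin rate = I per kb so the per-kb nucleation rate is ``I_kb_min``)
    with an origin-licensing margin of ``v * max(t)`` beyond each end, so the
    scoring window behaves like a segment of an unbounded fiber. Returns, per
    time, the mean replicated fraction and raw fork density with their
    Monte-Carlo standard errors and the closed-form expectations.
    """
    spacing = 1.0
    params = SimulationParams(
        n_fibers=n_fibers,
        fiber_length_kb=fiber_length_kb,
        lic_spacing_kb=spacing,
        fork_speed_kb_per_min=v,
        firing_rate_per_origin_per_min=I_kb_min * spacing,
        late_cluster_fraction=0.0,
        suppression_mock=1.0,
        suppression_depleted=1.0,
        sample_times_min=tuple(times),
        seed=seed,
    )
    margin = v * max(times)
    out: dict[float, dict[str, float]] = {}
    for ti, t in enumerate(params.sample_times_min):
        fracs = np.empty(n_fibers)
        dens = np.empty(n_fibers)
        for i in range(n_fibers):
            rng = _fiber_rng(seed, 0, ti, i)
            fib = simulate_fiber(
                params, "mock", t, rng, fiber_id=f"kjma_t{ti}_f{i}", margin_kb=margin
            )
            fracs[i] = fib.replicated_kb / fib.length_kb
            dens[i] = raw_fork_count(fib) / fib.length_kb
        out[float(t)] = {
            "fraction_mean": float(fracs.mean()),
            "fraction_se": float(fracs.std(ddof=1) / math.sqrt(n_fibers)),
            "fraction_expected": kjma_fraction(I_kb_min, v, t),
            "fork_density_mean": float(dens.mean()),
            "fork_density_se": float(dens.std(ddof=1) / math.sqrt(n_fibers)),
            "fork_density_expected": kjma_fork_density(I_kb_min, v, t),
        }
    return out


# ---------------------------------------------------------------------------
# output dialect


def write_fiber_table(fibers: Iterable[Fiber], path) -> None:
    """Write the fiber tract TSV (one row per tract; kb, 3-decimal fixed).

    Fibers with no tracts emit a single row with empty tract fields so they
    still count toward totals downstream. Coordinates are snapped to the
    3-decimal (1 bp) grid: tracts that round to zero width are dropped and
    tracts that abut after rounding are merged.
    """
    with open(path, "w") as fh:
        fh.write(
            "condition\ttime_min\tfiber_id\tfiber_length_kb\t"
            "tract_start_kb\ttract_end_kb\n"
        )
        for fib in fibers:
            prefix = f"{fib.condition}\t{fib.time_min:g}\t{fib.fiber_id}\t{fib.length_kb:.3f}"
            rounded: list[tuple[float, float]] = []
            for a, b in fib.tracts:
                ra, rb = round(a, 3), round(b, 3)
                if rb <= ra:
                    continue
                if rounded and ra <= rounded[-1][1]:
                    rounded[-1] = (rounded[-1][0], max(rounded[-1][1], rb))
                else:
                    rounded.append((ra, rb))
            if not rounded:
                fh.write(f"{prefix}\t\t\n")
            else:
                for a, b in rounded:
                    fh.write(f"{prefix}\t{a:.3f}\t{b:.3f}\n")


def write_manifest(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"params": params.to_dict(), "seed": params.seed}, fh)


def read_manifest(path) -> SimulationParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    d = dict(data["params"])
    d["sample_times_min"] = tuple(d["sample_times_min"])
    return SimulationParams(**d)
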