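"""Bulk DNA-synthesis (incorporation) kinetics.

Each egg extract replicates with its own kinetics, so raw incorporation time
courses from different experiments are made comparable by normalising every
series to its own maximum (percent of maximal incorporation). The normalised
scale is then partitioned into four S-phase bins — early (0-25], mid
(25-50], late (50-75], very late (75-100] percent — and depleted/mock
incorporation ratios at matched time points are grouped by the bin of the
mock (reference) series and tested against 1 with an exact Wilcoxon
signed-rank test.

The synthetic generator emulates the study's nascent-strand experiments:
sigmoidal (nucleation-and-growth shaped) cumulative incorporation, a
depleted condition that runs ahead of mock by a per-bin fold effect, and
multiplicative log-normal measurement noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import wilcoxon_vs_1

__all__ = [
    "IncorporationSeries",
    "BinnedRatios",
    "BIN_LABELS",
    "total_synthesis_ng_per_ul",
    "normalize_to_max",
    "assign_bin",
    "paired_bin_ratios",
    "simulate_incorporation_experiments",
    "read_series_csv",
    "write_ratio_csv",
]

BIN_LABELS = ("early", "mid", "late", "very_late")
# default per-bin depleted/mock fold effects of the emulated depletion
DEFAULT_BIN_EFFECTS: Mapping[str, float] = {
    "early": 1.8,
    "mid": 1.7,
    "late": 1.6,
    "very_late": 1.2,
}
NG_PER_NMOL_NUCLEOTIDE = 330.0


@dataclass
class IncorporationSeries:
    """One experiment x condition incorporation time course."""

    experiment_id: str
    condition: str
    times_min: tuple[float, ...]
    values: tuple[float, ...]
    normalized_pct: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.values):
            raise ValueError("times and values must have equal length")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("times_min must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("incorporation values must be >= 0")


@dataclass(frozen=True)
class BinnedRatios:
    """Depleted/mock ratios grouped into the four S-phase bins."""

    bins: tuple[str, ...]
    ratios: dict[str, tuple[float, ...]]
    n: dict[str, int]
    p: dict[str, float]


def total_synthesis_ng_per_ul(
    frac_incorporated: float,
    dCTP_pool_uM: float = 50.0,
    reaction_vol_ul: float = 1.0,
) -> float:
    """Convert fraction of label incorporated to synthesised DNA, ng/µl.

    ng/µl = 4 (nucleotides per dNTP) x pool (µM = pmol/µl) x fraction
    x 0.330 ng/pmol of nucleotide. The endogenous dCTP pool of egg extract
    defaults to 50 µM. ``reaction_vol_ul`` does not enter the per-µl value;
    multiply by it for total ng.
    """
    if not 0.0 <= frac_incorporated <= 1.0:
        raise ValueError("frac_incorporated must be in [0, 1]")
    if dCTP_pool_uM <= 0 or reaction_vol_ul <= 0:
        raise ValueError("pool and volume must be strictly positive")
    return 4.0 * dCTP_pool_uM * frac_incorporated * NG_PER_NMOL_NUCLEOTIDE / 1000.0


def normalize_to_max(series: IncorporationSeries) -> IncorporationSeries:
    """Scale a series to percent of its own maximum incorporation."""
    peak = max(series.values)
    if peak <= 0:
        raise ValueError(f"{series.experiment_id}/{series.condition}: all-zero series")
    series.normalized_pct = tuple(100.0 * v / peak for v in series.values)
    return series


def assign_bin(pct: float) -> str:
    """S-phase bin of a normalised incorporation percentage.

    [0, 25] -> early; (25, 50] -> mid; (50, 75] -> late; (75, 100] -> very
    late. Exact boundary values go to the lower bin.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct <= 25.0:
        return "early"
    if pct <= 50.0:
        return "mid"
    if pct <= 75.0:
        return "late"
    return "very_late"


def paired_bin_ratios(
    depleted: Sequence[IncorporationSeries],
    mock: Sequence[IncorporationSeries],
) -> BinnedRatios:
    """Per-bin depleted/mock incorporation ratios across experiments.

    Series are paired by experiment_id; ratios of raw values are taken at
    shared time points and binned by the mock series' normalised percentage
    (mock is the reference kinetics). Points where mock is 0 are skipped
    with a warning. Each bin's ratios are tested against 1 with a two-tailed
    Wilcoxon signed-rank (exact for n <= 25).
    """
    mock_by_exp = {s.experiment_id: s for s in mock}
    ratios: dict[str, list[float]] = {b: [] for b in BIN_LABELS}
    any_shared = False
    for dep in depleted:
        m = mock_by_exp.get(dep.experiment_id)
        if m is None:
            continue
        if m.normalized_pct is None:
            normalize_to_max(m)
        shared = sorted(set(dep.times_min) & set(m.times_min))
        if shared:
            any_shared = True
        d_by_t = dict(zip(dep.times_min, dep.values))
        m_by_t = dict(zip(m.times_min, m.values))
        pct_by_t = dict(zip(m.times_min, m.normalized_pct))
        for t in shared:
            if m_by_t[t] == 0:
                warnings.warn(
                    f"{dep.experiment_id}: mock incorporation 0 at t={t}, point skipped",
                    stacklevel=2,
                )
                continue
            ratios[assign_bin(pct_by_t[t])].append(d_by_t[t] / m_by_t[t])
    if not any_shared:
        raise ValueError("no shared time points between depleted and mock series")
    p: dict[str, float] = {}
    for b in BIN_LABELS:
        if not ratios[b]:
            p[b] = float("nan")  # empty bin: no test
        elif all(r == 1.0 for r in ratios[b]):
            p[b] = 1.0  # no depleted/mock difference at any point
        else:
            p[b] = wilcoxon_vs_1(ratios[b])
    return BinnedRatios(
        bins=BIN_LABELS,
        ratios={b: tuple(v) for b, v in ratios.items()},
        n={b: len(ratios[b]) for b in BIN_LABELS},
        p=p,
    )


def simulate_incorporation_experiments(
    n_experiments: int = 8,
    times_min: Sequence[float] = tuple(range(15, 181, 15)),
    bin_effects: Mapping[str, float] | float = None,
    tau_min: float = 75.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[IncorporationSeries], list[IncorporationSeries]]:
    """Synthetic paired depleted/mock incorporation experiments.

    Mock cumulative incorporation follows 1 - exp(-(t/tau)^2); the depleted
    value at each time is the mock value times the fold effect of the bin
    that time falls into (scalar or per-bin mapping; defaults emulate
    depletion of a late-origin brake: 1.8/1.7/1.6/1.2 from early to very
    late). Multiplicative log-normal noise of scale ``noise_sd`` is applied
    independently to every measurement. Returns (depleted, mock) lists.
    """
    if bin_effects is None:
        bin_effects = DEFAULT_BIN_EFFECTS
    if isinstance(bin_effects, (int, float)):
        bin_effects = {b: float(bin_effects) for b in BIN_LABELS}
    rng = np.random.default_rng(seed)
    t = np.asarray(times_min, dtype=float)
    depleted: list[IncorporationSeries] = []
    mock: list[IncorporationSeries] = []
    for i in range(n_experiments):
        # per-extract kinetics vary: jitter tau by ~10%
        tau = tau_min * rng.lognormal(0.0, 0.1)
        base = 1.0 - np.exp(-((t / tau) ** 2))
        pct = 100.0 * base / base.max()
        effect = np.array([bin_effects[assign_bin(p)] for p in pct])
        m_vals = base * rng.lognormal(0.0, noise_sd, size=t.size)
        d_vals = base * effect * rng.lognormal(0.0, noise_sd, size=t.size)
        exp_id = f"exp{i + 1:02d}"
        mock.append(
            IncorporationSeries(exp_id, "mock", tuple(t), tuple(m_vals))
        )
        depleted.append(
            IncorporationSeries(exp_id, "depleted", tuple(t), tuple(d_vals))
        )
    return depleted, mock


def read_series_csv(path) -> list[IncorporationSeries]:
    """Read `experiment_id, condition, time_min, value` CSV into series."""
    df = pd.read_csv(path)
    required = {"experiment_id", "condition", "time_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (exp, cond), grp in df.groupby(["experiment_id", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            IncorporationSeries(
                str(exp),
                str(cond),
                tuple(grp["time_min"].astype(float)),
                tuple(grp["value"].astype(float)),
            )
        )
    return out


def write_ratio_csv(binned: BinnedRatios, path) -> None:
    rows = []
    for b in binned.bins:
        for r in binned.ratios[b]:
            rows.append({"bin": b, "ratio": r})
    pd.DataFrame(rows).to_csv(path, index=False)
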