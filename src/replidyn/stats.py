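"""Depleted/mock ratio statistics shared across the pipeline.

All tests are two-tailed; significance is conventionally read against
alpha = 0.05 and no multiple-testing correction is applied. Exact null
distributions are used where feasible — Mann-Whitney when the smaller group
has at most 8 tie-free observations, Wilcoxon signed-rank up to n = 25
tie-free nonzero differences — and normal approximations with tie/continuity
corrections otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatioResult",
    "EnrichmentRecord",
    "FociCounts",
    "ratio_of_stats",
    "one_sample_t_vs_1",
    "mann_whitney",
    "wilcoxon_vs_1",
    "ratio_result",
    "enrichment_filter",
    "foci_pattern_ratio",
    "compare_foci_patterns",
]

MW_EXACT_MAX_N = 8
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class RatioResult:
    """A labelled set of depleted/mock ratios with its test against 1."""

    label: str
    values: tuple[float, ...]
    n: int
    mean: float
    sd: float
    test: str
    statistic: float
    p_two_tailed: float


@dataclass(frozen=True)
class EnrichmentRecord:
    """Co-IP protein abundance in target vs control pulldowns."""

    protein_id: str
    abundance_target: float
    abundance_control: float

    def __post_init__(self) -> None:
        if self.abundance_target < 0 or self.abundance_control < 0:
            raise ValueError(f"{self.protein_id}: abundances must be >= 0")

    @property
    def ratio(self) -> float:
        if self.abundance_control > 0:
            return self.abundance_target / self.abundance_control
        return math.inf if self.abundance_target > 0 else math.nan


@dataclass(frozen=True)
class FociCounts:
    """Replication-foci pattern counts for one retina."""

    retina_id: str
    condition: str
    n_early: int
    n_mid: int
    n_late: int

    def __post_init__(self) -> None:
        if min(self.n_early, self.n_mid, self.n_late) < 0:
            raise ValueError("foci counts must be >= 0")


def ratio_of_stats(depleted_stats, mock_stats, metric: str) -> list[float]:
    """Elementwise depleted/mock ratios of a named metric at matched times.

    Inputs are sequences of objects exposing ``time_min`` and the metric as
    an attribute (e.g. CombingStats) or mappings with those keys.
    """

    def get(obj, key):
        if isinstance(obj, Mapping):
            return obj[key]
        return getattr(obj, key)

    mock_by_t = {get(s, "time_min"): s for s in mock_stats}
    dep_by_t = {get(s, "time_min"): s for s in depleted_stats}
    if set(mock_by_t) != set(dep_by_t):
        raise ValueError(
            f"unmatched time points: depleted {sorted(dep_by_t)} vs mock {sorted(mock_by_t)}"
        )
    ratios = []
    for t in sorted(mock_by_t):
        m = float(get(mock_by_t[t], metric))
        d = float(get(dep_by_t[t], metric))
        if m <= 0:
            raise ValueError(f"mock {metric} is {m} at time {t}; ratio undefined")
        ratios.append(d / m)
    return ratios


def one_sample_t_vs_1(values: Sequence[float]) -> tuple[float, int, float]:
    """One-sample t of the mean against the theoretical ratio 1.

    Returns (t, df, two-tailed p). Requires n >= 2 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test requires n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("one-sample t-test undefined for zero variance")
    res = sps.ttest_1samp(x, popmean=1.0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def _has_ties(*groups: np.ndarray) -> bool:
    pooled = np.concatenate(groups)
    return np.unique(pooled).size < pooled.size


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U.

    Exact null when the smaller group has <= 8 observations and there are no
    ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two nonempty groups")
    exact = min(x.size, y.size) <= MW_EXACT_MAX_N and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_vs_1(values: Sequence[float]) -> float:
    """Two-tailed Wilcoxon signed-rank of ratios against 1.

    Values equal to 1 are dropped. Exact null for n <= 25 tie-free nonzero
    differences, normal approximation with continuity correction otherwise.
    """
    x = np.asarray(values, dtype=float)
    d = x[x != 1.0] - 1.0
    if d.size == 0:
        raise ValueError("wilcoxon_vs_1 requires at least one value != 1")
    exact = d.size <= WILCOXON_EXACT_MAX_N and not _has_ties(np.abs(d))
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return float(res.pvalue)


def ratio_result(label: str, values: Sequence[float], test: str = "one_sample_t_vs_1") -> RatioResult:
    """Summarise a ratio set with the named test against 1."""
    vals = tuple(float(v) for v in values)
    x = np.asarray(vals)
    if test == "one_sample_t_vs_1":
        stat, _, p = one_sample_t_vs_1(vals)
    elif test == "wilcoxon_vs_1":
        p = wilcoxon_vs_1(vals)
        stat = math.nan
    else:
        raise ValueError(f"unknown one-sample test {test!r}")
    return RatioResult(
        label=label,
        values=vals,
        n=len(vals),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if len(vals) > 1 else math.nan,
        test=test,
        statistic=stat,
        p_two_tailed=p,
    )


def enrichment_filter(
    records: Iterable[EnrichmentRecord],
    fold_threshold: float = 3.0,
    min_target_abundance: float = 1.0,
) -> list[EnrichmentRecord]:
    """Keep proteins enriched >= ``fold_threshold`` in target vs control co-IP.

    A protein absent from the control is infinitely enriched and is kept
    whenever its target abundance reaches ``min_target_abundance``.
    """
    kept = []
    for r in records:
        if r.abundance_control > 0:
            if r.ratio >= fold_threshold:
                kept.append(r)
        elif r.abundance_target >= min_target_abundance:
            kept.append(r)
    return kept


def foci_pattern_ratio(counts: FociCounts) -> float:
    """(mid + late) / early replication-foci pattern ratio for one retina."""
    if counts.n_early == 0:
        raise ValueError(f"{counts.retina_id}: no early-pattern foci; ratio undefined")
    return (counts.n_mid + counts.n_late) / counts.n_early


def compare_foci_patterns(
    counts: Iterable[FociCounts], condition_a: str, condition_b: str
) -> tuple[list[float], list[float], float, float]:
    """Per-retina (mid+late)/early ratios per condition, compared by Mann-Whitney.

    Retinas without early-pattern foci are excluded with a warning. Returns
    (ratios_a, ratios_b, U, p_two_tailed).
    """
    groups: dict[str, list[float]] = {condition_a: [], condition_b: []}
    for c in counts:
        if c.condition not in groups:
            continue
        if c.n_early == 0:
            warnings.warn(
                f"retina {c.retina_id}: no early-pattern foci, excluded", stacklevel=2
            )
            continue
        groups[c.condition].append(foci_pattern_ratio(c))
    u, p = mann_whitney(groups[condition_a], groups[condition_b])
    return groups[condition_a], groups[condition_b], u, p
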