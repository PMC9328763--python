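"""Per-nucleus fluorescence quantification.

Replication in intact nuclei is read out as incorporation of a fluorescent
nucleotide; each Hoechst-defined nucleus ROI yields an integrated density
and an area, and every slide contributes one mean background level per unit
area. Corrected total fluorescence is

    CTF = integrated density - area x mean slide background.

Negative CTFs (nuclei dimmer than background) are retained in means —
truncating them would bias condition ratios — and merely flagged. The
depletion effect is summarised per experiment as the ratio of mean CTFs,
depleted over mock, and the experiment-level ratios are tested against 1
with a two-tailed one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import RatioResult, ratio_result

__all__ = [
    "NucleusRecord",
    "SlideBackground",
    "ctf",
    "ctf_table",
    "percent_positive",
    "condition_fold_change",
    "simulate_nucleus_table",
]


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus ROI measurement (arbitrary fluorescence units)."""

    nucleus_id: str
    experiment_id: str
    slide_id: str
    condition: str
    integrated_density: float
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"{self.nucleus_id}: area must be > 0")
        if self.integrated_density < 0:
            raise ValueError(f"{self.nucleus_id}: integrated density must be >= 0")


@dataclass(frozen=True)
class SlideBackground:
    slide_id: str
    mean_background: float

    def __post_init__(self) -> None:
        if self.mean_background < 0:
            raise ValueError(f"{self.slide_id}: background must be >= 0")


def _background_map(backgrounds: Iterable[SlideBackground]) -> dict[str, float]:
    return {b.slide_id: b.mean_background for b in backgrounds}


def ctf(record: NucleusRecord, background: SlideBackground) -> float:
    """Corrected total fluorescence of one nucleus (may be negative)."""
    if record.slide_id != background.slide_id:
        raise ValueError(
            f"slide mismatch: nucleus {record.nucleus_id} is on "
            f"{record.slide_id!r}, background is for {background.slide_id!r}"
        )
    return record.integrated_density - record.area * background.mean_background


def ctf_table(
    records: Sequence[NucleusRecord], backgrounds: Iterable[SlideBackground]
) -> pd.DataFrame:
    """Per-nucleus CTF table with a flag on negative values."""
    bg = _background_map(backgrounds)
    rows = []
    for r in records:
        if r.slide_id not in bg:
            raise ValueError(f"no background for slide {r.slide_id!r}")
        value = r.integrated_density - r.area * bg[r.slide_id]
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "experiment_id": r.experiment_id,
                "slide_id": r.slide_id,
                "condition": r.condition,
                "integrated_density": r.integrated_density,
                "area": r.area,
                "ctf": value,
                "negative_ctf": value < 0,
            }
        )
    return pd.DataFrame(rows)


def percent_positive(
    records: Sequence[NucleusRecord],
    backgrounds: Iterable[SlideBackground],
    threshold: float = 0.0,
) -> float:
    """Percentage of nuclei with CTF strictly above ``threshold``."""
    if not records:
        raise ValueError("percent_positive requires at least one record")
    df = ctf_table(records, backgrounds)
    return 100.0 * float((df["ctf"] > threshold).sum()) / len(df)


def condition_fold_change(
    records: Sequence[NucleusRecord],
    backgrounds: Iterable[SlideBackground],
    depleted: str = "depleted",
    mock: str = "mock",
) -> RatioResult:
    """Per-experiment depleted/mock ratio of mean CTF, tested against 1.

    Every experiment must contain both conditions and a strictly positive
    mock mean CTF. The experiment-level ratios are summarised with a
    two-tailed one-sample t-test against the theoretical mean 1.
    """
    df = ctf_table(records, backgrounds)
    ratios = []
    for exp, grp in df.groupby("experiment_id", sort=True):
        means = grp.groupby("condition")["ctf"].mean()
        if depleted not in means or mock not in means:
            raise ValueError(f"experiment {exp!r} lacks one of the two conditions")
        if means[mock] <= 0:
            raise ValueError(f"experiment {exp!r}: mock mean CTF {means[mock]} <= 0")
        ratios.append(float(means[depleted] / means[mock]))
    return ratio_result("ctf_fold_change", ratios, test="one_sample_t_vs_1")


def simulate_nucleus_table(
    n_nuclei: int = 80,
    condition_effect: float = 1.5,
    noise_params: Mapping[str, float] | None = None,
    seed: int = 0,
    n_experiments: int = 6,
) -> tuple[list[NucleusRecord], list[SlideBackground]]:
    """Synthetic nucleus ROI tables for paired mock/depleted experiments.

    Per nucleus: area ~ log-normal around ``area_mean``; true signal =
    area x intensity, with per-nucleus log-normal intensity of scale
    ``intensity_sd`` around ``intensity_mean`` (times ``condition_effect``
    in the depleted condition); integrated density = signal + area x slide
    background, so CTF recovers the signal exactly up to the background
    estimate. One slide per experiment x condition, each with its own
    background level. Reproducible given ``seed``.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    p = {
        "area_mean": 200.0,
        "area_sd_log": 0.15,
        "intensity_mean": 25.0,
        "intensity_sd": 0.4,
        "background_mean": 10.0,
        "background_sd_log": 0.2,
    }
    if noise_params:
        p.update(noise_params)
    rng = np.random.default_rng(seed)
    records: list[NucleusRecord] = []
    backgrounds: list[SlideBackground] = []
    for e in range(n_experiments):
        exp_id = f"exp{e + 1:02d}"
        for condition, effect in (("mock", 1.0), ("depleted", condition_effect)):
            slide_id = f"{exp_id}_{condition}"
            bg = p["background_mean"] * rng.lognormal(0.0, p["background_sd_log"])
            backgrounds.append(SlideBackground(slide_id, float(bg)))
            areas = p["area_mean"] * rng.lognormal(0.0, p["area_sd_log"], size=n_nuclei)
            intensity = (
                p["intensity_mean"]
                * effect
                * rng.lognormal(0.0, p["intensity_sd"], size=n_nuclei)
            )
            signal = areas * intensity
            for i in range(n_nuclei):
                records.append(
                    NucleusRecord(
                        nucleus_id=f"{slide_id}_n{i:04d}",
                        experiment_id=exp_id,
                        slide_id=slide_id,
                        condition=condition,
                        integrated_density=float(signal[i] + areas[i] * bg),
                        area=float(areas[i]),
                    )
                )
    return records, backgrounds
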