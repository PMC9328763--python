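#!/usr/bin/env python
"""Combing calculus over the simulated fibers; depleted/mock ratios.

Reads the tract table from 01_simulate_fibers.py, applies the eye/gap
scoring rules (1-kb thresholds), pools per condition x time, and tests the
depleted/mock fork-density and replicated-fraction ratios against 1.
"""

import argparse
import json
from pathlib import Path

from replidyn import AnalysisConfig, aggregate, call_eyes, fiber_summary, read_fiber_table
from replidyn.combing import write_combing_stats, write_fiber_summaries
from replidyn.stats import ratio_of_stats, ratio_result


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = AnalysisConfig()
    fibers = read_fiber_table(args.in_dir / "fibers.tsv")
    summaries = [fiber_summary(call_eyes(f, cfg)) for f in fibers]
    groups: dict[tuple[str, float], list] = {}
    for f in fibers:
        groups.setdefault((f.condition, f.time_min), []).append(f)
    stats = {
        key: aggregate(fs, cfg, condition=key[0], time_min=key[1])
        for key, fs in sorted(groups.items())
    }

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_fiber_summaries(summaries, args.out_dir / "fiber_summaries.tsv")
    write_combing_stats(
        stats.values(),
        args.out_dir / "combing_stats.tsv",
        args.out_dir / "combing_stats.json",
    )

    times = sorted({t for _, t in stats})
    mock = [stats[("mock", t)] for t in times]
    dep = [stats[("depleted", t)] for t in times]
    results = {}
    for metric in ("fork_density_per_100kb", "replicated_fraction"):
        ratios = ratio_of_stats(dep, mock, metric)
        res = ratio_result(f"{metric}_ratio", ratios)
        results[res.label] = {
            "per_time": dict(zip(map(str, times), ratios)),
            "mean": res.mean, "p_two_tailed": res.p_two_tailed,
        }
        print(f"{res.label}: " + ", ".join(
            f"t={t:.0f}: {r:.2f}" for t, r in zip(times, ratios)
        ) + f"  (mean {res.mean:.2f}, t-test vs 1 p = {res.p_two_tailed:.3g})")
    for t in times:
        print(f"  % unreplicated fibers at t={t:.0f}: mock "
              f"{stats[('mock', t)].pct_unreplicated_fibers:.1f}, depleted "
              f"{stats[('depleted', t)].pct_unreplicated_fibers:.1f}")
    with open(args.out_dir / "depletion_ratios.json", "w") as fh:
        json.dump(results, fh, indent=1)
    print(f"wrote {args.out_dir / 'combing_stats.tsv'} and depletion_ratios.json")


if __name__ == "__main__":
    main()
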