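"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most literal method available —
event-by-event physical simulation, pairwise interval scanning, or full
enumeration of null distributions — sharing no code with the package paths
it checks.
"""

from __future__ import annotations

from itertools import combinations, product


# ---------------------------------------------------------------------------
# replication geometry: event-driven simulation with explicit passive firing


def event_driven_replicate(events, v, t, length_kb):
    """Replicated tracts at time t, processing origins in firing order.

    An origin whose position is already covered at its firing time is
    passively replicated and discarded; fired origins grow bidirectionally
    at speed v. Returns merged tracts clipped to [0, length_kb].
    """
    pending = sorted([(tf, x) for x, tf in events if tf < t])
    fired = []  # (x, tf) actually fired
    for tf, x in pending:
        covered = any(
            abs(x - xf) <= v * (tf - tff) for xf, tff in fired
        )
        if not covered:
            fired.append((x, tf))
    intervals = []
    for x, tf in fired:
        a, b = max(0.0, x - v * (t - tf)), min(length_kb, x + v * (t - tf))
        if b > a:
            intervals.append((a, b))
    return merge_intervals(intervals)


def merge_intervals(intervals):
    out = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# combing calculus, applied sentence by sentence


def brute_eye_calls(length_kb, tracts, min_eye_kb=1.0, min_gap_kb=1.0, tol_kb=0.0):
    """Literal scoring of one fiber's tracts.

    Repeatedly join any two adjacent tracts whose unlabelled gap is shorter
    than min_gap_kb (a sub-threshold gap is not a real gap); drop tracts
    shorter than min_eye_kb; a surviving tract touching an extremity is a
    terminal track worth one fork (zero if it touches both), anything else
    is an eye worth two forks.

    Returns (eyes, terminal, discarded, fork_count).
    """
    tracts = sorted((float(a), float(b)) for a, b in tracts)
    changed = True
    while changed:
        changed = False
        for i in range(len(tracts) - 1):
            if tracts[i + 1][0] - tracts[i][1] < min_gap_kb:
                tracts[i : i + 2] = [(tracts[i][0], tracts[i + 1][1])]
                changed = True
                break
    eyes, terminal, discarded = [], [], []
    forks = 0
    for a, b in tracts:
        if b - a < min_eye_kb:
            discarded.append((a, b))
        else:
            left = a <= tol_kb
            right = b >= length_kb - tol_kb
            if left and right:
                terminal.append((a, b))
            elif left or right:
                terminal.append((a, b))
                forks += 1
            else:
                eyes.append((a, b))
                forks += 2
    return eyes, terminal, discarded, forks


def brute_fiber_summary(length_kb, tracts, **kw):
    eyes, terminal, discarded, forks = brute_eye_calls(length_kb, tracts, **kw)
    replicated = sum(b - a for a, b in eyes) + sum(b - a for a, b in terminal)
    mids = [(a + b) / 2 for a, b in eyes]
    eteds = [m2 - m1 for m1, m2 in zip(mids, mids[1:])]
    els = [b - a for a, b in eyes]
    return {
        "replicated_kb": replicated,
        "eye_lengths_kb": els,
        "eteds_kb": eteds,
        "origins_kb": mids,
        "fork_count": forks,
        "n_eyes": len(eyes),
    }


# ---------------------------------------------------------------------------
# exact test null distributions by full enumeration (tie-free inputs only)


def enum_mannwhitney_p(a, b):
    """Two-tailed exact Mann-Whitney p by enumerating all group labellings."""
    n, m = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(n + m), n):
        sa = set(idx)
        u = sum(1 for i in sa for j in range(n + m) if j not in sa and i > j)
        us.append(u)
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(lo, hi))


def enum_wilcoxon_p(diffs):
    """Two-tailed exact signed-rank p by enumerating all 2^n sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    rank_of = {
        abs(x): r
        for r, x in enumerate(sorted(d, key=abs), start=1)
    }
    w_obs = sum(rank_of[abs(x)] for x in d if x > 0)
    rs = [rank_of[abs(x)] for x in d]
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(rs, signs) if s))
    total = len(ws)
    lo = sum(1 for w in ws if w <= w_obs) / total
    hi = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_exact_size(n, alpha=0.05):
    """True type-I error of the exact two-tailed signed-rank test at alpha.

    Enumerates the null distribution of W+ for tie-free |differences| and
    returns P(p-value <= alpha) under the null.
    """
    rs = list(range(1, n + 1))
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(rs, signs) if s))
    total = len(ws)
    count = 0
    for w in ws:
        lo = sum(1 for x in ws if x <= w) / total
        hi = sum(1 for x in ws if x >= w) / total
        p = min(1.0, 2.0 * min(lo, hi))
        if p <= alpha:
            count += 1
    return count / total
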