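"""Independent brute-force oracles used by the test suite.

Everything here recomputes results by enumeration or per-base membership,
deliberately avoiding the code paths (and the libraries) the package uses.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# --- per-base interval oracles ---------------------------------------------


def base_set(intervals) -> set[tuple[str, int]]:
    """Explicit set of (chrom, base) covered by a list of intervals."""
    out = set()
    for iv in intervals:
        for b in range(iv.start, iv.end):
            out.add((iv.chrom, b))
    return out


def bin_states_per_base(intervals, bin_size: int) -> dict:
    """Majority state per bin, leftmost-interval tie-break, via base arrays."""
    per_bin: dict[tuple[str, int], dict[str, list]] = {}
    for rank, iv in enumerate(sorted(intervals, key=lambda v: (v.chrom, v.start))):
        for b in range(iv.start, iv.end):
            key = (iv.chrom, b // bin_size)
            d = per_bin.setdefault(key, {})
            state = str(iv.payload)
            if state not in d:
                d[state] = [0, rank]
            d[state][0] += 1
    out = {}
    for key, d in per_bin.items():
        out[key] = min(d, key=lambda s: (-d[s][0], d[s][1]))
    return out


def transition_matrices(normal_bins: dict, tumor_bins: dict, states):
    """Observed / expected / RES / NES by direct loops over shared bins."""
    shared = sorted(set(normal_bins) & set(tumor_bins))
    n = len(states)
    pos = {s: i for i, s in enumerate(states)}
    obs = np.zeros((n, n))
    for key in shared:
        obs[pos[normal_bins[key]], pos[tumor_bins[key]]] += 1
    total = obs.sum()
    exp = np.zeros((n, n))
    res = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            exp[i, j] = obs[i].sum() * obs[:, j].sum() / total
            if exp[i, j] > 0:
                res[i, j] = obs[i, j] / exp[i, j]
    nes = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                nes[i, j] = 1.0 if res[i, i] > 0 else np.nan
            elif np.isfinite(res[i, j]) and np.isfinite(res[j, i]) and res[j, i] > 0:
                nes[i, j] = res[i, j] / res[j, i]
    return obs, exp, res, nes


# --- exact 2x2 / hypergeometric enumeration --------------------------------


def hypergeom_pmf(k: int, n_total: int, k_total: int, n_draw: int) -> float:
    return (
        math.comb(k_total, k)
        * math.comb(n_total - k_total, n_draw - k)
        / math.comb(n_total, n_draw)
    )


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, total, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        pk = hypergeom_pmf(k, total, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


def hypergeom_upper_tail(k: int, n_total: int, k_total: int, n_draw: int) -> float:
    """P(X >= k) by direct summation."""
    return sum(
        hypergeom_pmf(j, n_total, k_total, n_draw)
        for j in range(k, min(k_total, n_draw) + 1)
    )


def cohen_kappa(set_a, set_b, universe) -> float:
    """Kappa from the explicit confusion counts."""
    n11 = n10 = n01 = n00 = 0
    for g in universe:
        ina, inb = g in set_a, g in set_b
        if ina and inb:
            n11 += 1
        elif ina:
            n10 += 1
        elif inb:
            n01 += 1
        else:
            n00 += 1
    n = len(universe)
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / n**2
    return (po - pe) / (1 - pe)


# --- survival oracles -------------------------------------------------------


def km_by_risk_sets(times, events):
    """Kaplan-Meier by explicit risk-set tabulation. Returns {t: S(t)}."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    s = 1.0
    out = {0.0: 1.0}
    for t in sorted(set(times)):
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & (events == 1)))
        if deaths:
            s *= 1 - deaths / at_risk
        out[float(t)] = s
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square via the O-E / V sums."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    event_times = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        d_a = int(np.sum((ta == t) & (ea == 1)))
        d_b = int(np.sum((tb == t) & (eb == 1)))
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return (o_minus_e**2) / var if var > 0 else 0.0


# --- subgroup voting oracle -------------------------------------------------

_ACTIVE = {"H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3"}


def subgroup_by_votes(marks: dict) -> str:
    """Recompute the active/poised/repressive label from first principles."""
    activating = sum(
        1 for m, d in marks.items() if (m in _ACTIVE and d == "up") or (m not in _ACTIVE and d == "down")
    )
    silencing = len(marks) - activating
    if silencing == 0:
        return "active"
    if activating == 0:
        return "repressive"
    return "poised"
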