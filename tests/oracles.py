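"""Brute-force reference implementations used as test oracles.

These are deliberately literal transcriptions of the rules, independent of
the package internals, so the fast implementations can be checked against
them exactly.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def flag_oracle(intervals, low=0.70, high=1.30, window=11):
    """Literal screening rule: an interval is suspect iff it is < low or
    > high times the mean of up to ``window`` neighbouring intervals
    centered on it, excluding itself, truncated at the edges.

    Returns (ratios, suspect) as plain Python lists.
    """
    intervals = list(float(v) for v in intervals)
    n = len(intervals)
    half = window // 2
    ratios, suspect = [], []
    for i in range(n):
        neigh = []
        for j in range(i - half, i + half + 1):
            if j == i or j < 0 or j >= n:
                continue
            neigh.append(intervals[j])
        mavg = sum(neigh) / len(neigh)
        r = intervals[i] / mavg
        ratios.append(r)
        suspect.append(r < low or r > high)
    return ratios, suspect


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating every C(n+m, n) assignment
    of the pooled ranks to the first sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(a)
    w_obs = float(ranks[:n].sum())
    mu = n * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in combinations(range(len(pooled)), n):
        w = float(ranks[list(comb)].sum())
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def biplane_reference(area_2ch, area_4ch, long_axis):
    """Direct transcription of V = (8 / 3 pi) * A1 * A2 / L."""
    return 8.0 * area_2ch * area_4ch / (3.0 * np.pi * long_axis)


def match_events(det_times, det_classes, true_times, true_labels, tol_s=0.02):
    """Greedy 1-1 matching of detected premature beats to injected ones.

    Returns (n_true, n_matched, n_correct_class, n_false, confusion dict).
    """
    used = set()
    matched = correct = false = 0
    confusion = {}
    for dt, dc in zip(det_times, det_classes):
        hit = None
        for i, (tt, tl) in enumerate(zip(true_times, true_labels)):
            if i in used:
                continue
            if abs(dt - tt) < tol_s:
                hit = (i, tl)
                break
        if hit is None:
            false += 1
            continue
        used.add(hit[0])
        matched += 1
        if dc == hit[1]:
            correct += 1
        else:
            confusion[(hit[1], dc)] = confusion.get((hit[1], dc), 0) + 1
    return len(true_times), matched, correct, false, confusion
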