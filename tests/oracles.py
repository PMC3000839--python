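"""Independent brute-force oracles used to validate the package's algorithms.

These deliberately share no code with nfkin: plain-Python rescans of the
same definitions, kept simple enough to verify by eye.
"""

from itertools import combinations

import numpy as np


def brute_force_labels(times, positions, eps, frame_interval_s):
    """Per-interval labels by a literal one-interval-at-a-time scan."""
    labels = []
    for k in range(len(times) - 1):
        dt = times[k + 1] - times[k]
        dx = positions[k + 1] - positions[k]
        if dt > 1.5 * frame_interval_s:
            labels.append("U")
        elif dx > eps:
            labels.append("A")
        elif dx < -eps:
            labels.append("R")
        else:
            labels.append("P")
    return labels


def brute_force_bouts(times, positions, eps, frame_interval_s):
    """Run-length scan over interval labels.

    Returns tuples (direction, start_s, end_s, distance, truncated) where
    truncated is 'start' if the bout includes the first interval, 'end' if it
    includes the last, else 'none'.
    """
    labels = brute_force_labels(times, positions, eps, frame_interval_s)
    n = len(labels)
    bouts = []
    run = None  # (label, first_interval_index, last_interval_index)
    for k, lab in enumerate(labels + ["STOP"]):
        if run is not None and lab != run[0]:
            first, last = run[1], run[2]
            dist = sum(abs(positions[i + 1] - positions[i])
                       for i in range(first, last + 1))
            if first == 0:
                trunc = "start"
            elif last == n - 1:
                trunc = "end"
            else:
                trunc = "none"
            direction = "anterograde" if run[0] == "A" else "retrograde"
            bouts.append((direction, times[first], times[last + 1], dist, trunc))
            run = None
        if lab in ("A", "R"):
            run = (lab, run[1], k) if run else (lab, k, k)
    return bouts


def mw_u_statistic(x, y):
    """U of x by direct pair counting with half-credit for ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_exact_pvalue(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free input).

    Enumerates every assignment of the pooled values to the two groups,
    builds the null distribution of U, and doubles the smaller tail
    (the null is symmetric without ties), capping at 1.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    n1 = len(x)
    u_obs = mw_u_statistic(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(mw_u_statistic(gx, gy))
    us = np.array(us)
    p_lo = np.mean(us <= u_obs + 1e-12)
    p_hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def random_track_arrays(rng, frame_interval_s=4.0, eps=0.131):
    """Arbitrary synthetic (times, positions) exercising all label kinds.

    Displacements mix sub-threshold jitter, near-threshold values and
    directed steps; occasional multi-frame gaps are inserted.
    """
    n_int = int(rng.integers(2, 60))
    kinds = rng.integers(0, 4, n_int)
    dx = np.empty(n_int)
    dx[kinds == 0] = rng.normal(0.0, eps / 3, np.sum(kinds == 0))          # jitter
    dx[kinds == 1] = rng.choice([-1, 1], np.sum(kinds == 1)) * rng.uniform(
        0.5 * eps, 1.5 * eps, np.sum(kinds == 1))                           # boundary
    dx[kinds == 2] = rng.uniform(2 * eps, 2.0, np.sum(kinds == 2))          # antero
    dx[kinds == 3] = -rng.uniform(2 * eps, 2.0, np.sum(kinds == 3))         # retro
    steps = np.where(rng.random(n_int) < 0.08,
                     rng.integers(2, 5, n_int), 1)                          # gaps
    times = np.concatenate([[0.0], np.cumsum(steps * frame_interval_s)])
    positions = np.concatenate([[0.0], np.cumsum(dx)])
    return times, positions
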