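"""Independent brute-force oracles and small builders used by the tests.

Everything here is deliberately implemented without the package's own
detection/estimation code paths: flood fill by explicit BFS over pixel
coordinates, the log-rank statistic from its per-event-time 2x2 table
construction, and hand-built survival cohorts.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd

from wormquant.survival import SurvivalCohort

_NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_fill_calls(pixels, threshold, min_size=3, connectivity=8):
    """Set of clusters (frozensets of (row, col)) >= threshold, by BFS."""
    pixels = np.asarray(pixels, dtype=float)
    nbrs = _NEIGHBORS_8 if connectivity == 8 else _NEIGHBORS_4
    fg = {
        (r, c)
        for r in range(pixels.shape[0])
        for c in range(pixels.shape[1])
        if pixels[r, c] >= threshold
    }
    seen: set = set()
    clusters = set()
    for start in fg:
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        members = []
        while queue:
            r, c = queue.popleft()
            members.append((r, c))
            for dr, dc in nbrs:
                nxt = (r + dr, c + dc)
                if nxt in fg and nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        if len(members) >= min_size:
            clusters.add(frozenset(members))
    return clusters


def logrank_chi2(times_a, observed_a, times_b, observed_b):
    """Two-group log-rank chi-square from the 2x2-per-event-time tables."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    observed_a = np.asarray(observed_a, dtype=bool)
    observed_b = np.asarray(observed_b, dtype=bool)
    event_times = np.unique(
        np.concatenate([times_a[observed_a], times_b[observed_b]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        n = n_a + n_b
        d_a = np.sum((times_a == t) & observed_a)
        d_b = np.sum((times_b == t) & observed_b)
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def make_cohort(
    death_times=(),
    censor_times=(),
    schedule=None,
    censor_code="censor:end-of-study",
    assay="lifespan",
):
    """Hand-built cohort: deaths and censors at the given (schedule) times."""
    death_times = list(death_times)
    censor_times = list(censor_times)
    if schedule is None:
        last = max(death_times + censor_times + [1])
        schedule = np.arange(1.0, float(last) + 1.0)
    rows = []
    for i, t in enumerate(death_times):
        rows.append({"worm_id": f"d{i}", "time": float(t), "event_code": "death"})
    for i, t in enumerate(censor_times):
        rows.append({"worm_id": f"c{i}", "time": float(t), "event_code": censor_code})
    return SurvivalCohort(
        records=pd.DataFrame(rows), schedule=np.asarray(schedule, float), assay=assay
    )


def empirical_survival(death_times, t):
    """Empirical survivor function (no censoring): P(T > t)."""
    death_times = np.asarray(death_times, dtype=float)
    return float(np.mean(death_times > t))
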