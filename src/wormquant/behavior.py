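"""Formula-defined behavioral and physiologic indices.

The three dopamine-dependent behaviors have fixed assay formulas:

* basal slowing   = (v_off - v_on) / v_off, the fractional slowing of
  crawling when worms encounter a bacterial lawn;
* ethanol avoidance = (n_control - n_ethanol) / (n_control + n_ethanol),
  from quadrant-preference counts 30 min after plating;
* area-restricted searching (ARS) ratio = (turns/worm at 5 min) /
  (turns/worm at 30 min), the decay of local-search turning after removal
  from food.

Event-series rates (defecation pBoc cycle length, pharyngeal pumping per
30 s) and plain tabulations (brood size, post-embryonic development time)
also live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BehaviorIndex",
    "basal_slowing_index",
    "ethanol_avoidance_index",
    "ars_ratio",
    "defecation_cycle_length",
    "pumping_rate",
    "brood_size",
    "ped_time",
]


@dataclass
class BehaviorIndex:
    """One assay summary: value, worm count, replicate and genotype labels."""

    assay: str
    value: float
    n_worms: int
    replicate: int = 0
    genotype: str = ""


def basal_slowing_index(v_off: float, v_on: float) -> float:
    """(v_off - v_on) / v_off; 0 means no slowing, negative values allowed."""
    if v_off <= 0:
        raise ValueError("off-food speed must be positive (index undefined at 0)")
    if v_on < 0:
        raise ValueError("on-food speed must be non-negative")
    return (v_off - v_on) / v_off


def ethanol_avoidance_index(n_control: int, n_ethanol: int) -> float:
    """(n_control - n_ethanol) / total, in [-1, 1]."""
    if n_control < 0 or n_ethanol < 0:
        raise ValueError("quadrant counts must be non-negative")
    total = n_control + n_ethanol
    if total < 1:
        raise ValueError("at least one scored worm is required")
    return (n_control - n_ethanol) / total


def ars_ratio(
    turns_5min: int, worms_5min: int, turns_30min: int, worms_30min: int
) -> float:
    """(turns/worm at 5 min) / (turns/worm at 30 min)."""
    for v in (turns_5min, turns_30min):
        if v < 0:
            raise ValueError("turn counts must be non-negative")
    if worms_5min <= 0 or worms_30min <= 0:
        raise ValueError("worm counts must be positive")
    rate_30 = turns_30min / worms_30min
    if rate_30 == 0:
        raise ValueError(
            "zero turn rate at 30 min: non-searching cohort, ARS ratio undefined"
        )
    return (turns_5min / worms_5min) / rate_30


def defecation_cycle_length(events: Sequence[float]) -> float:
    """Mean interval between consecutive pBoc contractions, seconds."""
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        raise ValueError("need at least 2 events to measure a cycle")
    return float(np.diff(events).mean())


def pumping_rate(events: Sequence[float], window: float = 30.0) -> float:
    """Pharyngeal pumps within ``window`` seconds, reported per 30 s."""
    if window <= 0:
        raise ValueError("window must be positive")
    events = np.asarray(events, dtype=float)
    count = int(np.sum(events <= window)) if events.size else 0
    return count * (30.0 / window)


def brood_size(daily_counts: Sequence[int]) -> int:
    """Total progeny over the reproductive span (plain tabulation)."""
    counts = np.asarray(daily_counts, dtype=int)
    if counts.size and (counts < 0).any():
        raise ValueError("progeny counts must be non-negative")
    return int(counts.sum())


def ped_time(hatch_time: float, l4_adult_time: float) -> float:
    """Post-embryonic development time: hatching to the L4-adult transition."""
    if l4_adult_time <= hatch_time:
        raise ValueError("L4-adult transition must come after hatching")
    return l4_adult_time - hatch_time
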