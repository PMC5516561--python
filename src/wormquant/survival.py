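"""Lifespan and stress-survival scoring with right censoring.

Scoring conventions follow standard *C. elegans* demography practice:
viability on lifespan plates is assessed every 2 days by prodding, heat
(35 deg C) and acute juglone survival hourly, chronic paraquat daily, and
osmotic stress (450-500 mM NaCl) once at the 48 h endpoint.  Worms that bag
(internal hatching of progeny) or rupture (expulsion of internal organs) are
censored at the observation where the event was scored -- they are not
counted as deaths.  Death times are recorded at the observation time at
which death was scored, so all event times lie on the assay's observation
schedule.

The product-limit (Kaplan-Meier) estimator, restricted-mean/median
summaries, and the two-group log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import optimize

__all__ = [
    "EVENT_DEATH",
    "RAW_INTERNAL_HATCHING",
    "RAW_RUPTURE",
    "RAW_ALIVE_AT_END",
    "CENSOR_INTERNAL_HATCHING",
    "CENSOR_RUPTURE",
    "CENSOR_END_OF_STUDY",
    "CENSOR_LOST",
    "ASSAY_LABELS",
    "SurvivalCohort",
    "SurvivalCurve",
    "apply_censor_rules",
    "km_estimate",
    "lifespan_summary",
    "logrank",
    "fraction_surviving_at",
    "fit_gompertz",
    "concat_cohorts",
]

EVENT_DEATH = "death"

# Raw (as-scored) special events; the censoring rule converts these.
RAW_INTERNAL_HATCHING = "internal-hatching"
RAW_RUPTURE = "rupture"
RAW_ALIVE_AT_END = "alive-at-end"

CENSOR_INTERNAL_HATCHING = "censor:internal-hatching"
CENSOR_RUPTURE = "censor:rupture"
CENSOR_END_OF_STUDY = "censor:end-of-study"
CENSOR_LOST = "censor:lost"

_RAW_TO_CENSOR = {
    RAW_INTERNAL_HATCHING: CENSOR_INTERNAL_HATCHING,
    RAW_RUPTURE: CENSOR_RUPTURE,
    RAW_ALIVE_AT_END: CENSOR_END_OF_STUDY,
}
_CENSOR_CODES = frozenset(
    {CENSOR_INTERNAL_HATCHING, CENSOR_RUPTURE, CENSOR_END_OF_STUDY, CENSOR_LOST}
)
VALID_EVENT_CODES = frozenset({EVENT_DEATH}) | frozenset(_RAW_TO_CENSOR) | _CENSOR_CODES

ASSAY_LABELS = ("lifespan", "heat", "juglone", "paraquat", "osmotic")

_RECORD_COLUMNS = ("worm_id", "time", "event_code")


@dataclass
class SurvivalCohort:
    """One terminal record per worm, plus the assay's observation schedule.

    ``records`` columns: worm_id, time, event_code.  All times must lie on
    ``schedule`` (deaths and censoring are only ever scored at observations).
    """

    records: pd.DataFrame
    schedule: np.ndarray
    assay: str = "lifespan"
    genotype: str = ""

    def __post_init__(self) -> None:
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.schedule.size == 0:
            raise ValueError("observation schedule must be non-empty")
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("observation schedule must be strictly increasing")
        if np.any(self.schedule < 0):
            raise ValueError("observation times must be non-negative")
        if self.assay not in ASSAY_LABELS:
            raise ValueError(f"unknown assay label {self.assay!r}")
        missing = set(_RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if self.records["worm_id"].duplicated().any():
            raise ValueError("each worm must have exactly one terminal record")
        times = self.records["time"].to_numpy(dtype=float)
        if np.any(times < 0):
            raise ValueError("event times must be non-negative")
        on_schedule = np.isclose(times[:, None], self.schedule[None, :]).any(axis=1)
        if not on_schedule.all():
            bad = times[~on_schedule][:5]
            raise ValueError(f"event times not on the observation schedule: {bad}")
        bad_codes = set(self.records["event_code"]) - VALID_EVENT_CODES
        if bad_codes:
            raise ValueError(f"unknown event codes: {sorted(bad_codes)}")

    @property
    def n(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        df = self.records.copy()
        df["assay"] = self.assay
        df["genotype"] = self.genotype
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schedule: Sequence[float]) -> "SurvivalCohort":
        df = pd.read_csv(path)
        assay = str(df["assay"].iloc[0]) if "assay" in df else "lifespan"
        genotype = str(df["genotype"].iloc[0]) if "genotype" in df else ""
        return cls(
            records=df[list(_RECORD_COLUMNS)].copy(),
            schedule=np.asarray(schedule, dtype=float),
            assay=assay,
            genotype=genotype,
        )


def concat_cohorts(cohorts: Iterable[SurvivalCohort]) -> SurvivalCohort:
    """Pool cohorts (e.g., biological replicates) into one, keeping ids unique."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("no cohorts to pool")
    frames = []
    for i, c in enumerate(cohorts):
        df = c.records.copy()
        df["worm_id"] = [f"r{i}:{w}" for w in df["worm_id"]]
        frames.append(df)
    return SurvivalCohort(
        records=pd.concat(frames, ignore_index=True),
        schedule=cohorts[0].schedule,
        assay=cohorts[0].assay,
        genotype=cohorts[0].genotype,
    )


def apply_censor_rules(raw: SurvivalCohort) -> SurvivalCohort:
    """Convert internal-hatching / rupture / alive-at-end records to censors.

    Worms that bagged or ruptured are not counted as deaths: they become
    right-censored at the observation time where the event was scored.
    Death records and already-censored records pass through unchanged, so
    the operation is idempotent.
    """
    codes = raw.records["event_code"]
    unknown = set(codes) - VALID_EVENT_CODES
    if unknown:
        raise ValueError(f"unknown event codes: {sorted(unknown)}")
    mapped = codes.map(lambda c: _RAW_TO_CENSOR.get(c, c))
    records = raw.records.copy()
    records["event_code"] = mapped
    return SurvivalCohort(
        records=records, schedule=raw.schedule, assay=raw.assay, genotype=raw.genotype
    )


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit curve with at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0.0:
            # guarantee S(0)=1 as a curve invariant
            self.times = np.concatenate([[0.0], self.times])
            self.survival = np.concatenate([[1.0], self.survival])
            self.at_risk = np.concatenate([[self.at_risk[0]], self.at_risk])
            self.events = np.concatenate([[0], self.events])
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")

    def survival_at(self, t):
        """S(t) of the right-continuous step function (vectorised)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def restricted_mean(self) -> float:
        """Area under the curve up to the last observed time."""
        return float(np.sum(self.survival[:-1] * np.diff(self.times)))

    def median(self) -> float:
        """Earliest time with S <= 0.5, or NaN when never reached."""
        below = self.survival <= 0.5
        if not below.any():
            return float("nan")
        return float(self.times[np.argmax(below)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(cohort: SurvivalCohort) -> SurvivalCurve:
    """Product-limit estimate with right censoring.

    The censoring rule is applied first (idempotent), so raw cohorts can be
    passed directly.  Ties are resolved events-before-censors at equal times,
    the standard product-limit convention.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    scored = apply_censor_rules(cohort)
    durations = scored.records["time"].to_numpy(dtype=float)
    observed = (scored.records["event_code"] == EVENT_DEATH).to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    return SurvivalCurve(
        times=np.asarray(table.index, dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
    )


def lifespan_summary(curve: SurvivalCurve) -> dict:
    """Restricted mean (area under KM up to last time) and median lifespan."""
    median = curve.median()
    return {
        "mean_lifespan": curve.restricted_mean(),
        "median_lifespan": median,
        "median_reached": bool(np.isfinite(median)),
    }


def logrank(a: SurvivalCohort, b: SurvivalCohort) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both cohorts must be non-empty")
    sa, sb = apply_censor_rules(a), apply_censor_rules(b)
    obs_a = (sa.records["event_code"] == EVENT_DEATH).to_numpy()
    obs_b = (sb.records["event_code"] == EVENT_DEATH).to_numpy()
    if not obs_a.any() and not obs_b.any():
        return 0.0, 1.0
    res = logrank_test(
        sa.records["time"].to_numpy(dtype=float),
        sb.records["time"].to_numpy(dtype=float),
        event_observed_A=obs_a,
        event_observed_B=obs_b,
    )
    return float(res.test_statistic), float(res.p_value)


def fraction_surviving_at(cohort: SurvivalCohort, t: float) -> float:
    """Censoring-aware KM survival at time ``t`` (e.g., the 48 h osmotic endpoint).

    Beyond the last observation the curve cannot be extrapolated; the value
    at the last observation is returned with a warning.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    curve = km_estimate(cohort)
    last = curve.times[-1]
    if t > last:
        warnings.warn(
            f"t={t} is beyond the last observation ({last}); returning the "
            "value at the last observation",
            stacklevel=2,
        )
        t = last
    return float(curve.survival_at(t))


def fit_gompertz(cohort: SurvivalCohort) -> tuple[float, float]:
    """Maximum-likelihood Gompertz fit (rate a, shape b).

    A death scored at observation t means the worm died in the interval
    (t_prev, t] between consecutive observations, so deaths contribute the
    interval-censored likelihood S(t_prev) - S(t); censored worms contribute
    S(t).  This removes the discretisation bias a coarse observation
    schedule would otherwise impose on the rate parameter.
    """
    scored = apply_censor_rules(cohort)
    times = scored.records["time"].to_numpy(dtype=float)
    observed = (scored.records["event_code"] == EVENT_DEATH).to_numpy()
    if not observed.any():
        raise ValueError("cannot fit a mortality law to a cohort with no deaths")
    sched = cohort.schedule
    idx = np.searchsorted(sched, times - 1e-9, side="left")
    prev = np.where(idx > 0, sched[np.clip(idx - 1, 0, None)], 0.0)

    def survival_fn(t: np.ndarray, a: float, b: float) -> np.ndarray:
        return np.exp(-(a / b) * np.expm1(b * t))

    def negloglik(params: np.ndarray) -> float:
        a, b = np.exp(params)
        s_prev = survival_fn(prev, a, b)
        s_t = survival_fn(times, a, b)
        with np.errstate(divide="ignore"):
            death_ll = np.log(np.maximum(s_prev - s_t, 1e-300))
            cens_ll = np.log(np.maximum(s_t, 1e-300))
        return -float(np.sum(np.where(observed, death_ll, cens_ll)))

    res = optimize.minimize(
        negloglik,
        x0=np.log([0.01, 0.2]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    a, b = np.exp(res.x)
    return float(a), float(b)
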