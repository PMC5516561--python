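"""Full-study orchestration: genotypes x assays x replicates, plus stats.

`run_study` re-enacts the whole experimental design on synthetic cohorts:
for every configured assay, genotype and biological replicate it generates
inputs with the `synth` module, quantifies them with the `survival`,
`locomotion`, `behavior` and `imaging` modules, and then performs the group
comparisons with the presentation conventions of SEM error bars and
significance stars (* P<0.05, ** P<0.01, *** P<0.001).

Statistics: index-type assays are compared by Welch's two-sample t-test
across biological replicate means; survival assays by the log-rank test on
the replicate-pooled cohorts.  No multiple-testing correction is applied
(reported in the run manifest).

Seeds: one master seed expands into per-(assay, genotype, replicate) child
seeds through numpy's SeedSequence keyed on the indices, so identical
configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior, imaging, locomotion, survival
from .genotypes import default_genotypes, make_genotype
from .gompertz import calibrate_rate
from .synth import (
    GenotypeSpec,
    ImageModel,
    PlantedPuncta,
    dopamine_neuron_image_model,
    gen_event_series,
    gen_fluor_image,
    gen_quadrant_counts,
    gen_survival_cohort,
    gen_worm_track,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "ComparisonResult",
    "run_study",
    "compare_groups",
    "neuron_loss_timecourse",
    "default_study_config",
    "null_study_config",
    "SURVIVAL_ASSAYS",
    "ASSAY_IDS",
]

# ---------------------------------------------------------------------------
# Assay-level constants (time units noted per assay)

LIFESPAN_SCHEDULE = np.arange(2.0, 82.0, 2.0)  # days, scored every 2 days
HEAT_SCHEDULE = np.arange(1.0, 15.0)  # hours, scored hourly at 35 C
JUGLONE_SCHEDULE = np.arange(1.0, 19.0)  # hours, 240 uM juglone
PARAQUAT_SCHEDULE = np.arange(1.0, 15.0)  # days, 2 mM paraquat
OSMOTIC_SCHEDULE = np.array([48.0])  # hours, single 48 h endpoint

# Control-level stress mortality (shape, mean survival); frailty scales rate.
_STRESS_LAW = {
    "heat": (0.4, 8.0, HEAT_SCHEDULE),
    "juglone": (0.35, 9.0, JUGLONE_SCHEDULE),
    "paraquat": (0.4, 4.0, PARAQUAT_SCHEDULE),
    "osmotic": (0.0, 1.0 / 0.0035, OSMOTIC_SCHEDULE),  # exponential hazard
}

SURVIVAL_ASSAYS = frozenset({"lifespan", "heat", "juglone", "paraquat", "osmotic"})


def _child_seed(master: int, *key: int) -> int:
    """Deterministic child seed (below 2^31) from a master seed and indices."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def _stress_mortality(spec: GenotypeSpec, stressor: str) -> tuple[float, float]:
    b, control_mean, _sched = _STRESS_LAW[stressor]
    base_a = calibrate_rate(b, control_mean)
    return base_a * spec.frailty(stressor), b


# ---------------------------------------------------------------------------
# Per-replicate assay implementations.  Each returns (value, n, cohort|None).


def _assay_lifespan(spec, n, seed, censor_prob=0.02):
    cohort = gen_survival_cohort(
        spec, n, LIFESPAN_SCHEDULE, censor_prob=censor_prob, seed=seed
    )
    return survival.km_estimate(cohort).restricted_mean(), n, cohort


def _assay_stress(stressor):
    def run(spec, n, seed, censor_prob=0.0):
        a, b = _stress_mortality(spec, stressor)
        cohort = gen_survival_cohort(
            spec, n, _STRESS_LAW[stressor][2], censor_prob=censor_prob, seed=seed,
            assay=stressor, mortality=(a, b),
        )
        if stressor == "osmotic":
            return survival.fraction_surviving_at(cohort, 48.0), n, cohort
        return survival.km_estimate(cohort).restricted_mean(), n, cohort

    return run


def _worm_speeds(spec_speed, n, rng, duration, fps, noise_sd, seed0):
    """Per-worm measured speeds: lognormal worm-to-worm variation, tracked."""
    sigma = 0.15
    targets = rng.lognormal(np.log(spec_speed) - 0.5 * sigma**2, sigma, size=n)
    speeds = []
    for i, target in enumerate(targets):
        track = gen_worm_track(
            speed=float(target), duration=duration, fps=fps, noise_sd=noise_sd,
            heading_deg=float(rng.uniform(0, 360)), seed=seed0 + i,
        )
        speeds.append(locomotion.compute_speed(track))
    return np.asarray(speeds)


def _assay_basal_slowing(spec, n, seed, duration=60.0, fps=8.0, noise_sd=0.003):
    rng = np.random.default_rng(seed)
    v_off = _worm_speeds(spec.speed_off_food, n, rng, duration, fps, noise_sd, seed * 2)
    v_on = _worm_speeds(spec.speed_on_food, n, rng, duration, fps, noise_sd,
                        seed * 2 + 1)
    index = behavior.basal_slowing_index(float(v_off.mean()), float(v_on.mean()))
    return index, n, None


def _assay_ethanol(spec, n, seed):
    counts = gen_quadrant_counts(spec.avoidance_strength, n, seed)
    return behavior.ethanol_avoidance_index(counts.control, counts.ethanol), n, None


def _planted_turn_track(rate_per_min, duration, fps, rng, seed):
    k = rng.poisson(rate_per_min * duration / 60.0)
    times = np.sort(rng.uniform(0.0, duration, size=k))
    angles = rng.uniform(100.0, 170.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    return gen_worm_track(
        speed=0.15, turn_events=list(zip(times, angles)), duration=duration,
        fps=fps, noise_sd=0.002, heading_deg=float(rng.uniform(0, 360)), seed=seed,
    )


def _assay_ars(spec, n, seed, duration=60.0, fps=8.0):
    rng = np.random.default_rng(seed)
    turns = {}
    for tp, rate in (("5min", spec.turn_rate_5min), ("30min", spec.turn_rate_30min)):
        total = 0
        for i in range(n):
            track = _planted_turn_track(rate, duration, fps, rng, seed + 7919 * i)
            total += len(locomotion.count_turns(track))
        # scale counts to per-minute turn rates before forming the ratio
        turns[tp] = total * 60.0 / duration
    value = behavior.ars_ratio(int(round(turns["5min"])), n,
                               int(round(turns["30min"])), n)
    return value, n, None


def _assay_thrashing(spec, n, seed, duration=30.0, fps=8.0):
    rng = np.random.default_rng(seed)
    counts = []
    for i in range(n):
        freq = max(0.2, rng.normal(spec.bend_freq_hz, 0.05 * spec.bend_freq_hz))
        track = gen_worm_track(
            speed=0.05, bend_freq=freq, duration=duration, fps=fps, seed=seed + i
        )
        counts.append(locomotion.count_thrashes(track))
    return float(np.mean(counts)), n, None


def _assay_pumping(spec, n, seed):
    rng = np.random.default_rng(seed)
    rates = []
    for i in range(n):
        events = gen_event_series(
            mean_interval=spec.pump_interval_s,
            jitter_sd=0.1 * spec.pump_interval_s,
            duration=30.0, seed=seed + i,
        )
        rates.append(behavior.pumping_rate(events, window=30.0))
    return float(np.mean(rates)), n, None


def _assay_defecation(spec, n, seed):
    rates = []
    for i in range(n):
        events = gen_event_series(
            mean_interval=spec.defecation_interval_s,
            jitter_sd=0.08 * spec.defecation_interval_s,
            duration=10 * spec.defecation_interval_s, seed=seed + i,
        )
        rates.append(behavior.defecation_cycle_length(events))
    return float(np.mean(rates)), n, None


def _puncta_slots(r0, c0, r1, c1, spacing=8):
    rows = np.arange(r0 + spacing // 2, r1 - spacing // 2, spacing)
    cols = np.arange(c0 + spacing // 2, c1 - spacing // 2, spacing)
    return [(int(r), int(c)) for r in rows for c in cols]


def _aggregation_image(rate, shape, roi, rng, seed):
    """Plant Poisson-many punctae on a non-colliding slot grid inside roi."""
    slots = _puncta_slots(*roi)
    k = min(rng.poisson(rate), len(slots))
    chosen = rng.choice(len(slots), size=k, replace=False) if k else []
    punctae = [
        PlantedPuncta(
            center=slots[int(i)],
            pixel_count=int(rng.integers(3, 9)),
            amplitude=float(rng.uniform(2.0, 5.0)),
        )
        for i in chosen
    ]
    model = ImageModel(shape=shape, punctae=punctae)
    return gen_fluor_image(model, seed=seed), k


def _assay_vulva_puncta(spec, n, seed):
    rng = np.random.default_rng(seed)
    roi = (24, 24, 72, 72)
    counts = []
    for i in range(n):
        image, _k = _aggregation_image(spec.vulva_puncta_rate, (96, 96), roi, rng,
                                       seed + i)
        counts.append(
            imaging.count_punctae_in_roi(
                image, roi, background=image.ground_truth.background
            )
        )
    return float(np.mean(counts)), n, None


def _assay_wholeworm_puncta(spec, n, seed):
    rng = np.random.default_rng(seed)
    counts = []
    for i in range(n):
        image, _k = _aggregation_image(
            spec.wholeworm_puncta_rate, (96, 128), (8, 8, 88, 120), rng, seed + i
        )
        counts.append(
            len(imaging.detect_punctae(image,
                                       background=image.ground_truth.background))
        )
    return float(np.mean(counts)), n, None


def _assay_lipofuscin(spec, n, seed, age_days=9.0):
    rng = np.random.default_rng(seed)
    values = []
    polygon = [(20, 10), (20, 118), (44, 118), (44, 10)]
    for i in range(n):
        lift = spec.lipofuscin_rate * age_days
        model = ImageModel(
            shape=(64, 128), worm_mask_polygon=polygon,
            body_amplitude=lift / 5.0,  # background_sd = 5 by default
        )
        image = gen_fluor_image(model, seed=seed + i)
        values.append(imaging.lipofuscin_intensity(image))
    return float(np.mean(values)), n, None


ASSAY_FUNCS: dict[str, Callable] = {
    "lifespan": _assay_lifespan,
    "heat": _assay_stress("heat"),
    "juglone": _assay_stress("juglone"),
    "paraquat": _assay_stress("paraquat"),
    "osmotic": _assay_stress("osmotic"),
    "basal_slowing": _assay_basal_slowing,
    "ethanol_avoidance": _assay_ethanol,
    "ars": _assay_ars,
    "thrashing": _assay_thrashing,
    "pumping": _assay_pumping,
    "defecation": _assay_defecation,
    "vulva_puncta": _assay_vulva_puncta,
    "wholeworm_puncta": _assay_wholeworm_puncta,
    "lipofuscin": _assay_lipofuscin,
}
ASSAY_IDS = tuple(ASSAY_FUNCS)

# Worms per replicate: stated assay minima where the protocol gives one.
DEFAULT_N = {
    "lifespan": 30,
    "heat": 20,
    "juglone": 20,
    "paraquat": 20,
    "osmotic": 20,
    "basal_slowing": 50,
    "ethanol_avoidance": 40,
    "ars": 20,
    "thrashing": 10,
    "pumping": 10,
    "defecation": 5,
    "vulva_puncta": 10,
    "wholeworm_puncta": 10,
    "lipofuscin": 10,
}


# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Study design: genotype panel, assay list, replicates, seeds, outputs."""

    genotypes: dict[str, GenotypeSpec]
    assays: Sequence[str]
    comparison_pairs: Sequence[tuple[str, str]] = ()
    replicates: int = 3
    n_per_assay: dict[str, int] = field(default_factory=dict)
    assay_params: dict[str, dict] = field(default_factory=dict)
    master_seed: int = 0
    output_dir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 3:
            raise ValueError("a minimum of three biological replicates is required")
        unknown = [a for a in self.assays if a not in ASSAY_FUNCS]
        if unknown:
            raise ValueError(f"unknown assay ids: {unknown}")
        for pair in self.comparison_pairs:
            for g in pair:
                if g not in self.genotypes:
                    raise ValueError(f"comparison names unknown genotype {g!r}")

    def n_for(self, assay: str) -> int:
        return int(self.n_per_assay.get(assay, DEFAULT_N[assay]))

    def to_yaml(self) -> str:
        payload = {
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "assays": list(self.assays),
            "comparison_pairs": [list(p) for p in self.comparison_pairs],
            "n_per_assay": dict(self.n_per_assay),
            "assay_params": {k: dict(v) for k, v in self.assay_params.items()},
            "genotypes": {
                name: {
                    k: (dict(v) if isinstance(v, dict) else v)
                    for k, v in asdict(spec).items()
                }
                for name, spec in self.genotypes.items()
            },
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        payload = yaml.safe_load(text)
        genotypes = {
            name: GenotypeSpec(**fields)
            for name, fields in payload["genotypes"].items()
        }
        return cls(
            genotypes=genotypes,
            assays=payload["assays"],
            comparison_pairs=[tuple(p) for p in payload.get("comparison_pairs", [])],
            replicates=payload.get("replicates", 3),
            n_per_assay=payload.get("n_per_assay", {}),
            assay_params=payload.get("assay_params", {}),
            master_seed=payload.get("master_seed", 0),
        )


@dataclass
class ComparisonResult:
    """One genotype contrast within one assay."""

    assay: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    effect: float  # mean_a - mean_b
    sem_a: float
    sem_b: float
    test: str
    statistic: float
    p_value: float
    stars: str


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    assay: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Welch two-sample t-test on biological-replicate means, with SEMs."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 replicate values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        stat = 0.0 if p == 1.0 else np.inf
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(stat), float(p)
    return ComparisonResult(
        assay=assay, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        effect=float(a.mean() - b.mean()),
        sem_a=float(stats.sem(a)), sem_b=float(stats.sem(b)),
        test="welch-t", statistic=stat, p_value=p, stars=_stars(p),
    )


@dataclass
class StudyResult:
    assay_results: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    cohorts: dict = field(default_factory=dict)  # (assay, genotype) -> pooled cohort

    def replicate_values(self, assay: str, genotype: str) -> np.ndarray:
        df = self.assay_results
        sel = (df["assay"] == assay) & (df["genotype"] == genotype)
        return df.loc[sel, "value"].to_numpy()

    def mean_value(self, assay: str, genotype: str) -> float:
        return float(self.replicate_values(assay, genotype).mean())


def run_study(config: StudyConfig) -> StudyResult:
    """Execute every assay x genotype x replicate and compare the groups."""
    rows = []
    cohort_lists: dict[tuple[str, str], list] = {}
    for ai, assay in enumerate(config.assays):
        fn = ASSAY_FUNCS[assay]
        params = config.assay_params.get(assay, {})
        n = config.n_for(assay)
        for gi, (gname, spec) in enumerate(config.genotypes.items()):
            for rep in range(config.replicates):
                seed = _child_seed(config.master_seed, ai, gi, rep)
                value, n_used, cohort = fn(spec, n, seed, **params)
                rows.append(
                    {"assay": assay, "genotype": gname, "replicate": rep,
                     "value": value, "n": n_used, "seed": seed}
                )
                if cohort is not None:
                    cohort_lists.setdefault((assay, gname), []).append(cohort)
    assay_results = pd.DataFrame(rows)

    pooled = {
        key: survival.concat_cohorts(cohorts) for key, cohorts in cohort_lists.items()
    }

    comp_rows = []
    for assay in config.assays:
        for ga, gb in config.comparison_pairs:
            vals_a = assay_results.query("assay == @assay and genotype == @ga")["value"]
            vals_b = assay_results.query("assay == @assay and genotype == @gb")["value"]
            comp = compare_groups(vals_a, vals_b, assay=assay, group_a=ga, group_b=gb)
            if assay in SURVIVAL_ASSAYS:
                stat, p = survival.logrank(pooled[(assay, ga)], pooled[(assay, gb)])
                comp.test, comp.statistic, comp.p_value = "logrank", stat, p
                comp.stars = _stars(p)
            comp_rows.append(asdict(comp))
    comparisons = pd.DataFrame(comp_rows)

    config_yaml = config.to_yaml()
    manifest = {
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "replicates": config.replicates,
        "assays": list(config.assays),
        "genotypes": list(config.genotypes),
        "multiple_testing_correction": "none",
    }
    result = StudyResult(
        assay_results=assay_results, comparisons=comparisons,
        manifest=manifest, cohorts=pooled,
    )
    if config.output_dir is not None:
        _write_outputs(config, result, config_yaml)
    return result


def _write_outputs(config: StudyConfig, result: StudyResult, config_yaml: str) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.assay_results.to_csv(out / "assay_results.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "config.yaml").write_text(config_yaml)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh)
    if config.make_plots:
        _write_plots(config, result, out)


def _write_plots(config: StudyConfig, result: StudyResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for assay in config.assays:
        fig, ax = plt.subplots(figsize=(6, 4))
        if assay in SURVIVAL_ASSAYS:
            for gname in config.genotypes:
                curve = survival.km_estimate(result.cohorts[(assay, gname)])
                ax.step(curve.times, 100 * curve.survival, where="post", label=gname)
            ax.set_xlabel("time")
            ax.set_ylabel("% survival")
        else:
            sub = result.assay_results[result.assay_results["assay"] == assay]
            means = sub.groupby("genotype", sort=False)["value"].mean()
            sems = sub.groupby("genotype", sort=False)["value"].sem()
            ax.bar(means.index, means.to_numpy(), yerr=sems.to_numpy(), capsize=3)
            ax.set_ylabel(assay)
            ax.tick_params(axis="x", rotation=45)
        ax.set_title(assay)
        if assay in SURVIVAL_ASSAYS:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"{assay}.png", dpi=120)
        plt.close(fig)


def neuron_loss_timecourse(
    spec: GenotypeSpec,
    days: Sequence[float],
    n: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean anterior GFP+ soma count vs age, via image generation + counting.

    Each of the 6 anterior somata survives to age ``day`` with probability
    exp(-loss_rate * (day - 1)): the complement is full on day 1 of
    adulthood and decays under the genotype's per-neuron hazard.  Somata
    images are generated and counted with the imaging module (not read off
    the simulator), so the detector is part of the loop.
    """
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = []
    for di, day in enumerate(days):
        p_alive = float(np.exp(-spec.neuron_loss_rate * max(0.0, day - 1.0)))
        counts = []
        for w in range(n):
            rng = np.random.default_rng(_child_seed(seed, di, w))
            alive = rng.random(6) < p_alive
            image = gen_fluor_image(
                dopamine_neuron_image_model(anterior_alive=alive.tolist()),
                seed=_child_seed(seed, di, w, 1),
            )
            survey = imaging.count_somata(image, region="anterior")
            counts.append(survey.anterior_count)
        counts = np.asarray(counts, dtype=float)
        rows.append(
            {"day": day, "mean_somata": counts.mean(),
             "sem": counts.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0, "n": n}
        )
    return pd.DataFrame(rows)


def default_study_config(master_seed: int = 0, **overrides) -> StudyConfig:
    """The study re-enactment: PD models +/- daf-2 against their controls.

    Five biological replicates are used (the protocol's three is a minimum;
    five gives the partial-rescue contrasts adequate power at the stated
    per-assay worm counts).
    """
    kwargs = dict(
        genotypes=default_genotypes(),
        assays=["lifespan", "heat", "osmotic", "basal_slowing",
                "ethanol_avoidance", "ars"],
        comparison_pairs=[
            ("asyn", "WT"),
            ("asyn;daf-2", "WT"),
            ("asyn;daf-2", "asyn"),
            ("lrrk2", "GFP-control"),
            ("lrrk2;daf-2", "GFP-control"),
            ("lrrk2;daf-2", "lrrk2"),
            ("lrrk2;daf-2;daf-16", "GFP-control"),
            ("daf-2", "WT"),
        ],
        replicates=5,
        master_seed=master_seed,
    )
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


def null_study_config(master_seed: int = 0) -> StudyConfig:
    """Zero-effect design: three relabeled copies of the same genotype.

    Used to check the false-positive (type-I error) behaviour of the
    comparison machinery.  Worm counts are reduced (the error rate does not
    depend on them) but eight replicates are used so the small-sample t
    approximation is accurate, and the quadrant assay scores enough worms
    that its index is effectively continuous.
    """
    wt = make_genotype("WT")
    return StudyConfig(
        genotypes={"A": wt, "B": wt, "C": wt},
        assays=["basal_slowing", "ethanol_avoidance", "ars"],
        comparison_pairs=[("B", "A"), ("C", "A")],
        replicates=8,
        n_per_assay={"basal_slowing": 12, "ethanol_avoidance": 200, "ars": 20},
        assay_params={"basal_slowing": {"duration": 20.0}},
        master_seed=master_seed,
    )
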