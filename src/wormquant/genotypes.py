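"""Default genotype parameterisations for the synthetic study.

The study design contrasts two transgenic Parkinson's models expressing a
human disease protein in dopamine neurons -- alpha-synuclein(A53T) and
LRRK2(G2019S) -- plus a body-wall-muscle alpha-syn:YFP aggregation model
("bw"), against wild-type / GFP-only controls, each optionally combined
with the long-lived insulin-IGF1 receptor mutant daf-2 and with loss of
the FOXO factor DAF-16.

Construction rules, applied in order:

1. Controls: Gompertz mean lifespan 20 d (shape 0.3/d); the PD transgenes
   leave lifespan unchanged; daf-2 multiplies mean lifespan by (1 + d)
   where d = daf16_active, i.e. doubling with intact DAF-16 and no benefit
   with DAF-16 lost.
2. PD deficits (slower neuron loss in alpha-syn than LRRK2, abolished basal
   slowing, no ethanol avoidance, flattened ARS, stress frailty) are
   rescued toward the control value by fraction r * d (complete rescue
   r = 1 for basal slowing and stress, partial r = 0.6-0.7 for ethanol
   avoidance, ARS, and neuron loss).
3. daf-2's own phenotypes: ~15% slower movement, mild ARS reduction, halved
   stress hazard, slower neuron loss and lipofuscin accumulation -- all
   scaled by d.

DAF-16 epistasis: d = 1 intact, 0.3 for RNAi knockdown (residual neuronal
expression), 0.0 for the deletion.
"""

from __future__ import annotations

from functools import lru_cache

from .gompertz import calibrate_rate
from .synth import GenotypeSpec

__all__ = ["make_genotype", "default_genotypes", "LIFESPAN_SHAPE", "PD_MODELS"]

LIFESPAN_SHAPE = 0.3  # Gompertz b, 1/day, shared across genotypes
CONTROL_MEAN_LIFESPAN = 20.0  # days; daf-2 doubles this

# Control (wild-type / GFP-only) phenotype
_CONTROL = dict(
    neuron_loss_rate=0.012,  # slow loss of GFP+ somata with age
    speed_on_food=0.05,
    speed_off_food=0.20,
    avoidance_strength=0.90,
    turn_rate_5min=4.0,
    turn_rate_30min=1.6,
    stress_frailty={"heat": 1.0, "juglone": 1.0, "paraquat": 1.0, "osmotic": 1.0},
    pump_interval_s=0.25,
    defecation_interval_s=50.0,
    bend_freq_hz=2.0,
    vulva_puncta_rate=0.0,
    wholeworm_puncta_rate=0.0,
    lipofuscin_rate=2.0,
)

# Per-model deficits (values replace the control entry)
PD_MODELS: dict[str, dict] = {
    "none": {},
    "asyn": dict(  # pan-neuronal-promoter alpha-syn(A53T) in dopamine neurons
        neuron_loss_rate=0.040,
        speed_on_food=0.18,  # basal slowing abolished
        avoidance_strength=0.50,  # no ethanol avoidance
        turn_rate_5min=2.2,
        turn_rate_30min=2.0,  # ARS flattened
        stress_frailty={"heat": 2.5, "juglone": 2.5, "paraquat": 2.5, "osmotic": 3.0},
        pump_interval_s=0.32,  # decreased pumping
        defecation_interval_s=58.0,  # slower defecation
    ),
    "lrrk2": dict(  # LRRK2(G2019S) + GFP in dopamine neurons
        neuron_loss_rate=0.060,
        speed_on_food=0.19,
        avoidance_strength=0.50,
        turn_rate_5min=2.2,
        turn_rate_30min=2.0,
        stress_frailty={"heat": 2.5, "juglone": 1.5, "paraquat": 1.5, "osmotic": 3.0},
        defecation_interval_s=44.0,  # more rapid defecation
        bend_freq_hz=2.2,  # trend toward increased thrashing
    ),
    "bw": dict(  # body-wall-muscle alpha-syn:YFP aggregation model
        stress_frailty={"heat": 1.5, "juglone": 1.0, "paraquat": 1.0, "osmotic": 5.0},
        bend_freq_hz=1.2,  # decreased movement
        vulva_puncta_rate=12.0,
        wholeworm_puncta_rate=7.0,
    ),
}

# Rescue fraction toward control per trait (applied times daf16_active)
_RESCUE = dict(
    basal_slowing=1.0,
    ethanol=0.6,
    ars=0.7,
    stress=1.0,
    neuron_loss=0.7,
    physiology=0.0,  # daf-2 does not rescue pumping/defecation/fertility
    vulva_puncta=0.45,
    bend=1.0,
)


def _rescued(pd_val: float, ctl_val: float, frac: float, d: float) -> float:
    return pd_val + frac * d * (ctl_val - pd_val)


@lru_cache(maxsize=None)
def make_genotype(
    name: str, pd_model: str = "none", daf2: bool = False, daf16_active: float = 1.0
) -> GenotypeSpec:
    """Build a GenotypeSpec from a PD model background and daf-2/daf-16 state."""
    if pd_model not in PD_MODELS:
        raise ValueError(f"unknown PD model {pd_model!r}")
    base = dict(_CONTROL)
    base.update(PD_MODELS[pd_model])
    d = daf16_active if daf2 else 0.0

    mean_lifespan = CONTROL_MEAN_LIFESPAN * (1.0 + d)
    a = calibrate_rate(LIFESPAN_SHAPE, mean_lifespan)

    ctl = _CONTROL
    neuron_loss = _rescued(
        base["neuron_loss_rate"], ctl["neuron_loss_rate"], _RESCUE["neuron_loss"], d
    ) / (1.0 + 1.5 * d)
    speed_on = _rescued(
        base["speed_on_food"], ctl["speed_on_food"], _RESCUE["basal_slowing"], d
    ) * (1.0 - 0.15 * d)
    speed_off = base["speed_off_food"] * (1.0 - 0.15 * d)
    avoidance = _rescued(
        base["avoidance_strength"], ctl["avoidance_strength"], _RESCUE["ethanol"], d
    )
    turns_5 = _rescued(
        base["turn_rate_5min"], ctl["turn_rate_5min"], _RESCUE["ars"], d
    ) * (1.0 - 0.1 * d)
    turns_30 = _rescued(base["turn_rate_30min"], ctl["turn_rate_30min"], _RESCUE["ars"], d)
    frailty = {
        stressor: _rescued(mult, ctl["stress_frailty"][stressor], _RESCUE["stress"], d)
        * (1.0 - 0.5 * d)
        for stressor, mult in base["stress_frailty"].items()
    }
    bend = _rescued(base["bend_freq_hz"], ctl["bend_freq_hz"], _RESCUE["bend"], d) * (
        1.0 - 0.15 * d
    )
    vulva = base["vulva_puncta_rate"] * (1.0 - _RESCUE["vulva_puncta"] * d)
    lipofuscin = base["lipofuscin_rate"] / (1.0 + d)

    return GenotypeSpec(
        name=name,
        gompertz_a=a,
        gompertz_b=LIFESPAN_SHAPE,
        neuron_loss_rate=neuron_loss,
        speed_on_food=speed_on,
        speed_off_food=speed_off,
        avoidance_strength=avoidance,
        turn_rate_5min=turns_5,
        turn_rate_30min=turns_30,
        stress_frailty=frailty,
        daf16_active=daf16_active if daf2 else 1.0,
        pump_interval_s=base["pump_interval_s"],
        defecation_interval_s=base["defecation_interval_s"],
        bend_freq_hz=bend,
        vulva_puncta_rate=vulva,
        wholeworm_puncta_rate=base["wholeworm_puncta_rate"],
        lipofuscin_rate=lipofuscin,
    )


def default_genotypes() -> dict[str, GenotypeSpec]:
    """The genotype panel of the full study re-enactment."""
    return {
        "WT": make_genotype("WT"),
        "GFP-control": make_genotype("GFP-control"),
        "daf-2": make_genotype("daf-2", daf2=True),
        "asyn": make_genotype("asyn", pd_model="asyn"),
        "asyn;daf-2": make_genotype("asyn;daf-2", pd_model="asyn", daf2=True),
        "lrrk2": make_genotype("lrrk2", pd_model="lrrk2"),
        "lrrk2;daf-2": make_genotype("lrrk2;daf-2", pd_model="lrrk2", daf2=True),
        "lrrk2;daf-2;daf-16": make_genotype(
            "lrrk2;daf-2;daf-16", pd_model="lrrk2", daf2=True, daf16_active=0.0
        ),
    }
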