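"""Synthetic cohorts, trajectories, event series, counts, and images.

Every generator plants known ground truth so the quantification modules can
be tested end to end without any external data:

* survival cohorts follow Gompertz mortality with genotype-specific rate and
  shape parameters, scored on an explicit observation schedule with
  bagging/rupture censoring;
* worm tracks advance at a commanded speed, change heading at planted turn
  events, and carry a sinusoidal bend-angle channel;
* fluorescence images plant punctae (compact clusters of exact pixel
  counts), somata (disks), a dendrite with blebs, over i.i.d. Gaussian
  background noise, on an unsigned-16-bit intensity range;
* quadrant counts and event-time series are simple binomial and
  truncated-normal renewal draws.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .gompertz import sample_gompertz
from .imaging import INTENSITY_MAX, FluorImage
from .locomotion import WormTrack
from .survival import (
    EVENT_DEATH,
    RAW_ALIVE_AT_END,
    RAW_INTERNAL_HATCHING,
    RAW_RUPTURE,
    SurvivalCohort,
)

__all__ = [
    "GenotypeSpec",
    "ImageModel",
    "PlantedPuncta",
    "PlantedSoma",
    "ImageGroundTruth",
    "QuadrantCounts",
    "gen_survival_cohort",
    "gen_worm_track",
    "gen_fluor_image",
    "gen_quadrant_counts",
    "gen_event_series",
    "cluster_offsets",
    "dopamine_neuron_image_model",
    "ANTERIOR_SOMA_TEMPLATE",
    "POSTERIOR_SOMA_TEMPLATE",
]


@dataclass(frozen=True)
class GenotypeSpec:
    """All synthetic parameters for one genotype.

    Mortality is Gompertz (rate ``gompertz_a``, shape ``gompertz_b``, per
    day); ``neuron_loss_rate`` is the per-day hazard of losing one anterior
    dopamine soma; speeds are mm/s; ``avoidance_strength`` is the
    probability that a worm settles in a control quadrant; turn rates are
    turns/worm/min at the 5 and 30 min ARS timepoints; ``stress_frailty``
    multiplies the assay-level mortality hazard per stressor; and
    ``daf16_active`` in [0, 1] scales every daf-2 benefit (1 = intact
    DAF-16, 0 = complete loss), modeling the insulin-pathway epistasis.
    The remaining fields parameterise physiologic-rate and aggregation
    assays (pump interval s, defecation interval s, swim bend frequency Hz,
    expected punctae per worm, lipofuscin accumulation per day).
    """

    name: str
    gompertz_a: float
    gompertz_b: float
    neuron_loss_rate: float
    speed_on_food: float
    speed_off_food: float
    avoidance_strength: float
    turn_rate_5min: float
    turn_rate_30min: float
    stress_frailty: Mapping[str, float] = field(default_factory=dict)
    daf16_active: float = 1.0
    pump_interval_s: float = 0.25
    defecation_interval_s: float = 50.0
    bend_freq_hz: float = 2.0
    vulva_puncta_rate: float = 0.0
    wholeworm_puncta_rate: float = 0.0
    lipofuscin_rate: float = 2.0

    def __post_init__(self) -> None:
        nonneg = {
            "gompertz_a": self.gompertz_a,
            "gompertz_b": self.gompertz_b,
            "neuron_loss_rate": self.neuron_loss_rate,
            "speed_on_food": self.speed_on_food,
            "speed_off_food": self.speed_off_food,
            "turn_rate_5min": self.turn_rate_5min,
            "turn_rate_30min": self.turn_rate_30min,
            "vulva_puncta_rate": self.vulva_puncta_rate,
            "wholeworm_puncta_rate": self.wholeworm_puncta_rate,
            "lipofuscin_rate": self.lipofuscin_rate,
        }
        for key, val in nonneg.items():
            if val < 0:
                raise ValueError(f"{key} must be non-negative")
        if not 0.0 <= self.avoidance_strength <= 1.0:
            raise ValueError("avoidance_strength must lie in [0, 1]")
        if not 0.0 <= self.daf16_active <= 1.0:
            raise ValueError("daf16_active must lie in [0, 1]")
        if any(v < 0 for v in self.stress_frailty.values()):
            raise ValueError("stress frailty multipliers must be non-negative")

    def frailty(self, stressor: str) -> float:
        return float(self.stress_frailty.get(stressor, 1.0))


def gen_survival_cohort(
    spec: GenotypeSpec,
    n: int,
    schedule: Sequence[float],
    censor_prob: float = 0.0,
    seed: int = 0,
    assay: str = "lifespan",
    mortality: Optional[tuple[float, float]] = None,
) -> SurvivalCohort:
    """Simulate one survival cohort on an explicit observation schedule.

    Death ages are Gompertz draws (``mortality`` = (a, b) overrides the
    spec's lifespan parameters, e.g. for stress assays); a death is scored
    at the first observation at or after the true death age, or the worm is
    censored alive at the last observation.  Independently, at every
    observation while alive the worm may be censored with probability
    ``censor_prob`` (bagging or rupture, chosen at random).  Event codes
    are raw -- `apply_censor_rules` performs the not-counted-as-deaths
    conversion downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("observation schedule must be non-empty")
    if np.any(np.diff(schedule) <= 0):
        raise ValueError("observation schedule must be strictly increasing")
    if not 0.0 <= censor_prob <= 1.0:
        raise ValueError("censor_prob must lie in [0, 1]")
    a, b = mortality if mortality is not None else (spec.gompertz_a, spec.gompertz_b)
    if a < 0 or b < 0:
        raise ValueError("mortality parameters must be non-negative")

    rng = np.random.default_rng(seed)
    death_age = sample_gompertz(a, b, n, rng)
    censor_flags = rng.random((n, schedule.size)) < censor_prob
    causes = rng.choice([RAW_INTERNAL_HATCHING, RAW_RUPTURE], size=n)

    death_obs = np.searchsorted(schedule, death_age, side="left")
    times = np.empty(n)
    codes: list[str] = []
    for w in range(n):
        d_idx = death_obs[w]
        cens = np.flatnonzero(censor_flags[w, : min(d_idx, schedule.size)])
        if cens.size:
            times[w] = schedule[cens[0]]
            codes.append(causes[w])
        elif d_idx < schedule.size:
            times[w] = schedule[d_idx]
            codes.append(EVENT_DEATH)
        else:
            times[w] = schedule[-1]
            codes.append(RAW_ALIVE_AT_END)

    records = pd.DataFrame(
        {"worm_id": [f"w{w}" for w in range(n)], "time": times, "event_code": codes}
    )
    return SurvivalCohort(records=records, schedule=schedule, assay=assay,
                          genotype=spec.name)


def gen_worm_track(
    speed: float,
    turn_events: Sequence[tuple[float, float]] = (),
    bend_freq: float = 0.0,
    duration: float = 10.0,
    fps: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    bend_amplitude: float = 30.0,
    start: tuple[float, float] = (0.0, 0.0),
    heading_deg: float = 0.0,
    worm_id: str = "w0",
) -> WormTrack:
    """Constant-speed track with planted instantaneous turns and bends.

    The track stores n_frames+1 samples at t = 0 .. duration, where
    n_frames = round(duration * fps), so path length equals
    speed * duration exactly in the noiseless case.  Each turn event
    (time s, angle deg) rotates the heading at the nearest frame; the
    bend-angle channel is ``bend_amplitude`` * sin(2 pi bend_freq t).
    Gaussian positional noise of SD ``noise_sd`` mm is added per coordinate.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if speed < 0 or noise_sd < 0 or bend_freq < 0:
        raise ValueError("speed, noise_sd and bend_freq must be non-negative")
    for t_ev, _ang in turn_events:
        if not 0.0 <= t_ev <= duration:
            raise ValueError(f"turn event at t={t_ev} outside [0, {duration}]")

    n_frames = int(round(duration * fps))
    # heading per step; the turn applies from its frame onward
    step_heading = np.full(n_frames, np.radians(heading_deg))
    for t_ev, ang in sorted(turn_events):
        frame = min(int(round(t_ev * fps)), n_frames - 1)
        step_heading[frame:] += np.radians(ang)

    steps = (speed / fps) * np.column_stack(
        [np.cos(step_heading), np.sin(step_heading)]
    )
    positions = np.vstack([[start], np.asarray(start) + np.cumsum(steps, axis=0)])

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        positions = positions + rng.normal(0.0, noise_sd, positions.shape)

    t = np.arange(n_frames + 1) / fps
    bend = bend_amplitude * np.sin(2 * np.pi * bend_freq * t) if bend_freq > 0 else None

    truth = {
        "speed": speed,
        "n_turns": len(turn_events),
        "turn_frames": [int(round(tv * fps)) for tv, _ in sorted(turn_events)],
        "turn_angles": [ang for _, ang in sorted(turn_events)],
        "n_bend_cycles": bend_freq * duration,
    }
    return WormTrack(worm_id=worm_id, fps=fps, positions=positions,
                     bend_angle=bend, ground_truth=truth)


@dataclass(frozen=True)
class PlantedPuncta:
    center: tuple[int, int]  # (row, col)
    pixel_count: int
    amplitude: float  # in background-SD units

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class PlantedSoma:
    center: tuple[int, int]
    radius: int = 3
    amplitude: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class ImageModel:
    """Declarative description of one synthetic fluorescence image."""

    shape: tuple[int, int] = (64, 64)
    background_mean: float = 100.0
    background_sd: float = 5.0
    worm_mask_polygon: Optional[Sequence[tuple[float, float]]] = None
    punctae: Sequence[PlantedPuncta] = ()
    somata: Sequence[PlantedSoma] = ()
    dendrite_path: Optional[Sequence[tuple[float, float]]] = None
    dendrite_amplitude: float = 3.0  # baseline above background, in SD units
    blebs: Sequence[float] = ()  # fractional positions along the dendrite path
    bleb_relative_amplitude: float = 2.0  # x dendrite baseline
    body_amplitude: float = 0.0  # uniform lift inside the mask (lipofuscin)

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        for f in self.blebs:
            if not 0.0 <= f <= 1.0:
                raise ValueError("bleb positions are fractions along the path")


@dataclass
class ImageGroundTruth:
    """Planted objects, exactly as rendered."""

    puncta_pixels: list[frozenset]
    puncta_sizes: list[int]
    puncta_amplitudes: list[float]
    soma_centers: list[tuple[int, int]]
    bleb_points: list[tuple[float, float]]
    background: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        """Sidecar table (one row per planted object) for CSV export."""
        rows = []
        for px, size, amp in zip(
            self.puncta_pixels, self.puncta_sizes, self.puncta_amplitudes
        ):
            r, c = min(px)
            rows.append(("puncta", r, c, size, amp))
        for r, c in self.soma_centers:
            rows.append(("soma", r, c, np.nan, np.nan))
        for r, c in self.bleb_points:
            rows.append(("bleb", r, c, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["kind", "row", "col", "size_px", "amplitude_sd"]
        )


def cluster_offsets(pixel_count: int) -> list[tuple[int, int]]:
    """Deterministic compact (near-square) cluster shape of exact size.

    Lattice offsets sorted by distance from the origin then by angle; any
    prefix of this ordering is 8-connected.
    """
    if pixel_count < 1:
        raise ValueError("pixel_count must be >= 1")
    radius = int(np.ceil(np.sqrt(pixel_count))) + 1
    grid = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
    ]
    grid.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2, np.arctan2(o[0], o[1])))
    return grid[:pixel_count]


def _chebyshev_adjacent(set_a: frozenset, set_b: frozenset) -> bool:
    return any(
        abs(ra - rb) <= 1 and abs(ca - cb) <= 1 for ra, ca in set_a for rb, cb in set_b
    )


def gen_fluor_image(model: ImageModel, seed: int = 0) -> FluorImage:
    """Render a synthetic image with exact, unambiguous planted ground truth.

    Background pixels are i.i.d. Normal(mean, sd) clipped to the 16-bit
    range.  Planted punctae/somata pixels are set to exactly
    mean + amplitude * sd (deterministic, so threshold behaviour is exact).
    Planted objects may not overlap or touch (8-connectivity) -- that would
    make ground-truth counts ambiguous -- and must lie inside the image.
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = model.shape
    pixels = rng.normal(model.background_mean, model.background_sd, size=model.shape)

    mask = None
    if model.worm_mask_polygon is not None:
        poly = np.asarray(model.worm_mask_polygon, dtype=float)
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=model.shape)
        mask = np.zeros(model.shape, dtype=bool)
        mask[rr, cc] = True
        if model.body_amplitude:
            pixels[mask] += model.body_amplitude * model.background_sd

    object_sets: list[frozenset] = []
    puncta_sets: list[frozenset] = []
    for p in model.punctae:
        px = frozenset(
            (p.center[0] + dr, p.center[1] + dc)
            for dr, dc in cluster_offsets(p.pixel_count)
        )
        if any(not (0 <= r < nrows and 0 <= c < ncols) for r, c in px):
            raise ValueError(f"puncta at {p.center} extends outside the image")
        puncta_sets.append(px)
        object_sets.append(px)

    soma_sets: list[frozenset] = []
    for s in model.somata:
        rr, cc = draw_disk(s.center, s.radius, shape=None)
        px = frozenset(zip(rr.tolist(), cc.tolist()))
        if any(not (0 <= r < nrows and 0 <= c < ncols) for r, c in px):
            raise ValueError(f"soma at {s.center} extends outside the image")
        soma_sets.append(px)
        object_sets.append(px)

    for i in range(len(object_sets)):
        for j in range(i + 1, len(object_sets)):
            if _chebyshev_adjacent(object_sets[i], object_sets[j]):
                raise ValueError(
                    "planted objects overlap or touch; ground truth would be ambiguous"
                )

    for p, px in zip(model.punctae, puncta_sets):
        value = model.background_mean + p.amplitude * model.background_sd
        for r, c in px:
            pixels[r, c] = value
    for s, px in zip(model.somata, soma_sets):
        value = model.background_mean + s.amplitude * model.background_sd
        for r, c in px:
            pixels[r, c] = value

    bleb_points: list[tuple[float, float]] = []
    if model.dendrite_path is not None:
        path = np.asarray(model.dendrite_path, dtype=float)
        baseline = (
            model.background_mean + model.dendrite_amplitude * model.background_sd
        )
        for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
            rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
            pixels[rr, cc] = baseline
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        for frac in model.blebs:
            s_pos = frac * cum[-1]
            r = float(np.interp(s_pos, cum, path[:, 0]))
            c = float(np.interp(s_pos, cum, path[:, 1]))
            rr, cc = draw_disk((r, c), 1.6, shape=model.shape)
            pixels[rr, cc] = baseline * model.bleb_relative_amplitude
            bleb_points.append((r, c))

    pixels = np.clip(pixels, 0.0, INTENSITY_MAX)
    truth = ImageGroundTruth(
        puncta_pixels=puncta_sets,
        puncta_sizes=[p.pixel_count for p in model.punctae],
        puncta_amplitudes=[p.amplitude for p in model.punctae],
        soma_centers=[s.center for s in model.somata],
        bleb_points=bleb_points,
        background=(model.background_mean, model.background_sd),
    )
    return FluorImage(pixels=pixels, body_mask=mask, ground_truth=truth)


#: Template soma centers (row, col) on a 64 x 128 canvas: the worm lies
#: horizontally, head left.  Anterior compartment: 4 CEP + 2 ADE; posterior:
#: 2 PDE.  Positions are spaced so planted disks never touch.
ANTERIOR_SOMA_TEMPLATE = [(12, 14), (28, 14), (44, 14), (20, 30), (36, 30), (28, 46)]
POSTERIOR_SOMA_TEMPLATE = [(20, 100), (40, 100)]


def dopamine_neuron_image_model(
    anterior_alive: Sequence[bool] = (True,) * 6,
    posterior_alive: Sequence[bool] = (True,) * 2,
    shape: tuple[int, int] = (64, 128),
    soma_radius: int = 3,
    soma_amplitude: float = 10.0,
    background_mean: float = 100.0,
    background_sd: float = 5.0,
) -> ImageModel:
    """Image model of a GFP dopamine-neuron survey worm.

    ``anterior_alive``/``posterior_alive`` flag which of the 6 anterior
    (CEP/ADE) and 2 posterior (PDE) somata are still present; a full
    complement plants all 8.
    """
    if len(anterior_alive) != 6 or len(posterior_alive) != 2:
        raise ValueError("expected 6 anterior and 2 posterior survival flags")
    somata = [
        PlantedSoma(center=c, radius=soma_radius, amplitude=soma_amplitude)
        for c, alive in zip(ANTERIOR_SOMA_TEMPLATE, anterior_alive)
        if alive
    ] + [
        PlantedSoma(center=c, radius=soma_radius, amplitude=soma_amplitude)
        for c, alive in zip(POSTERIOR_SOMA_TEMPLATE, posterior_alive)
        if alive
    ]
    return ImageModel(
        shape=shape,
        background_mean=background_mean,
        background_sd=background_sd,
        somata=somata,
    )


class QuadrantCounts(tuple):
    """(control, ethanol) worm counts from a quadrant-preference assay."""

    __slots__ = ()

    def __new__(cls, control: int, ethanol: int):
        return super().__new__(cls, (int(control), int(ethanol)))

    @property
    def control(self) -> int:
        return self[0]

    @property
    def ethanol(self) -> int:
        return self[1]


def gen_quadrant_counts(
    avoidance_strength: float, n: int, seed: int = 0
) -> QuadrantCounts:
    """Independently assign each worm to a control quadrant with the given
    probability; counts always sum to n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= avoidance_strength <= 1.0:
        raise ValueError("avoidance_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    control = int(rng.binomial(n, avoidance_strength))
    return QuadrantCounts(control, n - control)


def gen_event_series(
    mean_interval: float,
    jitter_sd: float = 0.0,
    duration: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Renewal event times with Normal(mean, jitter) intervals truncated
    positive; strictly increasing, within (0, duration]."""
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    while True:
        if jitter_sd == 0:
            dt = mean_interval
        else:
            dt = rng.normal(mean_interval, jitter_sd)
            while dt <= 0:  # truncate to positive support
                dt = rng.normal(mean_interval, jitter_sd)
        t += dt
        if t > duration + 1e-12:
            break
        times.append(t)
    return np.asarray(times)
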