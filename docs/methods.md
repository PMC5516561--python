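# Methods

`wormquant` re-implements, as one tested pipeline, the quantification
procedures of a *C. elegans* aging study of two genetic Parkinson's-disease
models — worms expressing human α-synuclein(A53T) or LRRK2(G2019S) in their
dopamine neurons, crossed to the long-lived insulin/IGF-1 receptor mutant
*daf-2* — together with a synthetic-data module that emulates the study's
cohorts so the whole analysis runs with no external data.  This note
documents the models, the parameters that matter, and the design choices
made where the underlying protocols leave the quantification open.

## Survival scoring

Lifespan is scored on a discrete observation schedule (every 2 days; hourly
for heat at 35 °C and acute juglone; daily for chronic paraquat; a single
48 h endpoint for osmotic stress).  A death is recorded at the observation
at which it was scored.  Worms with internal hatching of progeny (bagging)
or expulsion of internal organs are *censored* at that observation, never
counted as deaths; a worm alive at the last observation is censored
end-of-study.  Censoring causes are carried as an enum
(`censor:internal-hatching`, `censor:rupture`, `censor:end-of-study`,
`censor:lost`) so the rule is applied mechanically and idempotently.

Curves are product-limit (Kaplan–Meier) estimates with the standard
deaths-before-censors tie convention (lifelines supplies the estimator, the
log-rank test, and is cross-checked in the test suite against a hand-built
product-limit and a per-event-time 2×2 log-rank construction).  "Mean
lifespan" is the restricted mean — the area under the KM curve up to the
last observed time — because the assays themselves never define "average
lifespan"; the median is the earliest time with S ≤ 0.5 and is reported as
not-reached when the curve never crosses it.  Survival contrasts use the
two-group log-rank test; its null rejection rate is verified to sit within
the binomial confidence band of the nominal 5 % over 1000 simulated null
pairs.

Mortality follows the Gompertz law, h(t) = a·e^{bt}, the standard model for
worm demography.  Mean lifespan under this law is obtained by numerical
integration of the survival function, and `calibrate_rate` inverts it: given
shape b and a target mean, it solves for the rate a.  Defaults: shape
b = 0.3/day for all genotypes; control mean lifespan 20 days; *daf-2*
doubles the mean (rate recalibrated, not scaled ad hoc).  The b → 0 limit is
the exponential law and drives the osmotic endpoint assay.  `fit_gompertz`
is an interval-censored MLE — a death scored at observation t contributes
S(t_prev) − S(t) — which removes the discretisation bias a 2-day schedule
would otherwise impose.  A caveat on identifiability: a and b lie on a
likelihood ridge, so the rate parameter's per-cohort sampling CV at n = 1000
is ≈13 %; the estimator is unbiased (tested across seeds) but single-cohort
rate estimates are intrinsically loose.

## Locomotion

Tracks are time-ordered centroid positions (mm) at a known frame rate, with
an optional body-bend-angle channel.  A generated track stores
n_frames + 1 samples covering t = 0 … duration, so a noiseless track's path
length is exactly speed × duration.

* **Linking** is greedy nearest-neighbour per frame; links longer than
  `max_step` start new tracks, each detection is used at most once, and
  there is no gap bridging — a one-frame dropout deliberately splits a
  track.  Identity swaps at close crossings are allowed (track count, not
  identity, is the conserved quantity).
* **Speed** is the mean frame-to-frame displacement × fps after a centered
  moving-average smoothing of the positions (default 5 frames, 'valid'
  mode).  Smoothing suppresses the positive bias that per-frame positional
  noise adds to path length; planted speeds are recovered within 5 % at the
  default noise level.
* **Turns**: heading is measured over displacement vectors spanning 0.5 s
  of frames; the turn angle at frame i compares the window after i with the
  window before.  An event is a local maximum of that series *strictly
  exceeding* the threshold (the assay convention is "turns exceeding 90°"),
  with plateaus of contiguous supra-threshold frames merged into one event.
  Peak-height filtering makes the count monotone non-increasing in the
  threshold.  Zero-length windows (stationary worm) are skipped.
* **Thrashes**: one thrash per full bend cycle, counted as positive-going
  zero crossings of the mean-subtracted bend series.  Samples within
  numerical noise of zero are clamped so a cycle ending exactly on a sample
  boundary is not lost.

## Behavioral indices

The three dopamine-dependent indices are fixed formulas: basal slowing
(v_off − v_on)/v_off; ethanol avoidance (n_control − n_ethanol)/total (worms
in boundary zones are excluded from both counts and the total, since the
formula's total is control + ethanol); ARS ratio (turns/worm at 5 min) /
(turns/worm at 30 min), computed over full 1-minute recordings, averaging
over worms actually detected.  A zero 30-min turn rate makes the ARS ratio
undefined and is rejected as a non-searching cohort.  Defecation cycle
length is the mean inter-pBoc interval; pumping is an event count over 30 s.
Brood size and post-embryonic development time are plain tabulations.

## Image quantification

Images are single-channel intensity grids on the unsigned-16-bit range
(internally float; rounding to uint16 happens only on TIFF export so planted
amplitudes stay exact).  Background is estimated from pixels outside the
body mask when a mask exists, else from pixels below the image's Otsu split.
The Otsu path assumes some separable foreground: on an image containing
only noise, Otsu splits the noise mode itself and biases the background
low — a known limitation; supply a mask or an explicit background when
available.

* **Punctae** (α-synuclein:YFP aggregates): pixels at or above
  background mean + k·SD (k = 1, *inclusive*) are foreground; 8-connected
  components (diagonals join, config-exposed) of at least 3 pixels are
  calls.  In the degenerate SD = 0 case the threshold falls back to
  strictly-above-mean.  Note that under i.i.d. Gaussian noise the 1-SD rule
  intrinsically admits noise-only clusters (~16 % of pixels exceed the
  threshold), exactly as the rule would on a raw noisy image; recovery of
  planted objects is therefore evaluated by pixel-set coverage
  (`match_planted`), while correctness of the rule itself is established by
  exact equivalence to a brute-force flood-fill oracle.  The localized
  (vulva-region) count restricts calls by centroid, with a closed
  lower/left, open upper/right rectangle convention; it is an automated
  stand-in for what was originally a manual count.
* **Dopamine somata**: bright blobs above background + 5 SD with area in a
  size band, touching maxima merged by the component labeling; counts are
  clipped to the anatomical complement (6 anterior = 4 CEP + 2 ADE;
  8 total with 2 posterior PDE).  Zero detections are valid (full
  degeneration).  The detector's constants are package choices; correctness
  is assessed only against planted ground truth.
* **Dendritic blebs**: the intensity profile is sampled along the dendrite
  polyline at ~1 px spacing; blebs are profile maxima above
  median × `bleb_factor` (default 1.5) separated by ≥ 5 px.
* **Lipofuscin**: background-subtracted mean intensity over the body mask
  (or the at-or-above-Otsu region).

## Synthetic data

The generators plant known ground truth and are bit-reproducible given
(parameters, seed).  Survival cohorts draw Gompertz death ages by inverse
CDF and walk the observation schedule, applying per-observation
bagging/rupture censoring.  Tracks advance at a commanded speed, rotate the
heading instantaneously at planted turn events, and carry a sinusoidal bend
channel.  Images plant punctae as deterministic compact (near-square)
clusters of exact pixel count at exactly mean + amplitude·SD, somata as
disks, blebs as bumps along a drawn dendrite, over i.i.d. Gaussian
background noise; planted objects may not overlap *or touch* under
8-connectivity, which keeps ground-truth counts unambiguous.  Quadrant
counts are binomial; event series are truncated-normal renewals.

What the generators do **not** emulate: worm body postures, bacterial
lawns, optics (PSF, vignetting), spatially correlated backgrounds,
photobleaching, detection dropouts, or any real-image segmentation problem.
Passing tests therefore demonstrate that the quantification rules are
implemented exactly and recover planted effects at realistic sizes — not
that the detectors would segment real micrographs.

## Genotype parameterisation

Each genotype is a parameter bundle (`GenotypeSpec`).  Controls: mean
lifespan 20 d; speeds 0.20 mm/s off food vs 0.05 on food (basal slowing
0.75); avoidance strength 0.9 (index 0.8); ARS turn rates 4.0 → 1.6
turns/worm/min (ratio 2.5); soma-loss hazard 0.012/day.  PD models keep
normal lifespan but lose basal slowing and ethanol avoidance, flatten ARS,
accelerate soma loss (LRRK2 0.060/day > α-syn 0.040/day), and carry stress
frailty multipliers (heat 2.5×, osmotic 3×).  The body-wall α-syn:YFP
aggregation model adds vulva-region punctae (Poisson mean 12/worm) and a
strong osmotic frailty.

*daf-2* benefits are scaled by a DAF-16 activity scalar d ∈ [0, 1]
(1 intact, 0.3 RNAi knockdown with neuronal residual, 0 deletion),
reproducing the epistasis direction: lifespan ×(1 + d); deficits rescued
toward control by trait-specific fractions (complete for basal slowing and
stress, 0.6 for ethanol avoidance, 0.7 for ARS and neuron loss, the latter
further slowed by 1/(1 + 1.5d), calibrated so the LRRK2;daf-2 soma count at
day 30 resembles LRRK2 at day 5); plus daf-2's own phenotypes — ~15 % slower
movement, mild ARS reduction, halved stress hazard.  With d = 0 every
benefit vanishes and the genotype collapses onto its PD background.

## Study orchestration and statistics

`run_study` executes assays × genotypes × replicates, deriving each child
seed from the master seed via `SeedSequence` keyed on indices — identical
configurations reproduce byte-identical tables.  Index-type assays are
compared by Welch's t-test across biological-replicate means (matching the
SEM-bar + star presentation; stars at 0.05/0.01/0.001); survival assays by
log-rank on replicate-pooled cohorts.  No multiple-testing correction is
applied, and the run manifest says so.  Per-assay worm counts default to the
protocols' stated minima (20 worms for stress and ARS, ~50 for basal
slowing, 10–15 for imaging).  The default design uses five biological
replicates: three is the protocol's minimum, but at exactly three the
partial ARS rescue contrast is under-powered.

Two calibration facts worth knowing when reading outputs: Welch's t-test at
small replicate counts is mildly conservative (rejection ≈ 0.044 at n = 8 on
exactly normal data), and ratio-valued indices (ARS, basal slowing) are
slightly skewed at the replicate level, so the zero-effect re-enactment
stars ≈ 4 % of comparisons at α = 0.05 — the same order as nominal, with no
inflation.  The log-rank null is calibrated to within its binomial band.

## Problem sizes

Default sizes were chosen so the full test suite and the acceptance script
each complete in a few minutes on one CPU: 200 oracle images at 64×64;
1000 log-rank null pairs at 2×30 worms; lifespan-doubling at 2×500 worms;
the full study at 8 genotypes × 6 assays × 5 replicates; the zero-effect
calibration at 100–200 re-enactments of a reduced three-assay design.
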