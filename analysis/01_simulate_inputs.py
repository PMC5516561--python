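#!/usr/bin/env python
"""Write example synthetic inputs: cohorts, tracks, images with ground truth.

Everything downstream analyses consume can be regenerated from seeds; this
script materialises a small set of files to show the on-disk formats
(cohort/track CSVs, 16-bit TIFF images with truth-table sidecars).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wormquant.genotypes import default_genotypes
from wormquant.pipeline import LIFESPAN_SCHEDULE
from wormquant.synth import (
    ImageModel,
    PlantedPuncta,
    dopamine_neuron_image_model,
    gen_fluor_image,
    gen_survival_cohort,
    gen_worm_track,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    panel = default_genotypes()

    for name in ("WT", "daf-2", "asyn", "lrrk2"):
        cohort = gen_survival_cohort(panel[name], 30, LIFESPAN_SCHEDULE,
                                     censor_prob=0.02, seed=hash(name) % 2**31)
        path = OUT / f"lifespan_{name.replace(';', '_')}.csv"
        cohort.to_csv(path)
        print(f"wrote {cohort.n}-worm lifespan cohort for {name} -> {path.name}")

    track = gen_worm_track(speed=0.15, turn_events=[(10.0, 120.0), (25.0, -110.0)],
                           bend_freq=2.0, duration=60.0, noise_sd=0.003, seed=0)
    track.to_frame().to_csv(OUT / "track_example.csv", index=False)
    print(f"wrote example track ({track.n_frames} frames) -> track_example.csv")

    rng = np.random.default_rng(0)
    punctae = [
        PlantedPuncta(center=(int(r), int(c)), pixel_count=int(rng.integers(3, 9)),
                      amplitude=float(rng.uniform(2, 5)))
        for r in range(10, 60, 14) for c in range(10, 60, 14)
    ]
    image = gen_fluor_image(ImageModel(punctae=punctae), seed=1)
    image.to_tiff(OUT / "aggregates.tif")
    image.ground_truth.to_dataframe().to_csv(OUT / "aggregates.truth.csv",
                                             index=False)
    print(f"wrote aggregate image with {len(punctae)} planted punctae "
          "-> aggregates.tif (+ truth sidecar)")

    neurons = gen_fluor_image(dopamine_neuron_image_model(), seed=2)
    neurons.to_tiff(OUT / "dopamine_neurons.tif")
    print("wrote full-complement dopamine-neuron image -> dopamine_neurons.tif")


if __name__ == "__main__":
    main()
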