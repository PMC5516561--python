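#!/usr/bin/env python
"""Dopamine-dependent behavioral indices per genotype.

Runs the three behavior assays (basal slowing, ethanol avoidance,
area-restricted searching) plus the physiologic rates (thrashing, pumping,
defecation) through the track/event-series pipeline for every genotype and
tabulates replicate means with SEM.
"""

import warnings
from pathlib import Path

import pandas as pd

from wormquant.pipeline import StudyConfig, run_study
from wormquant.genotypes import default_genotypes

OUT = Path(__file__).resolve().parents[1] / "results" / "behavior"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    warnings.filterwarnings("ignore")
    config = StudyConfig(
        genotypes=default_genotypes(),
        assays=["basal_slowing", "ethanol_avoidance", "ars",
                "thrashing", "pumping", "defecation"],
        replicates=5,
        master_seed=7,
    )
    result = run_study(config)
    summary = (
        result.assay_results.groupby(["assay", "genotype"], sort=False)["value"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    summary.to_csv(OUT / "behavior_indices.csv", index=False)
    for assay in config.assays:
        sub = summary[summary["assay"] == assay]
        print(f"\n{assay} (replicate mean +/- SEM):")
        for _, row in sub.iterrows():
            print(f"  {row['genotype']:<22s} {row['mean']:8.3f} +/- {row['sem']:.3f}")
    print(f"\ntable written to {OUT / 'behavior_indices.csv'}")


if __name__ == "__main__":
    main()
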