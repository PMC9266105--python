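#!/usr/bin/env python
"""Rank factor importance for TVDI with a random forest.

Assembles the eight-factor sample table from the study scene at the 4x
analysis cell, fits a seeded 70/30 random-forest regression of mean-annual
TVDI on the factors, and reports the impurity-based importance ranking and
holdout skill.  A second fit on a planted table (response a function of
precipitation plus a weaker temperature effect, everything else noise)
demonstrates recovery of a known ranking, with the partial-dependence
curve of the dominant factor written alongside.
"""

import numpy as np
import pandas as pd

from tvdizone import SceneConfig, generate_scene
from tvdizone.pipeline import (PipelineConfig, annual_composites,
                               fit_zone_edges, tvdi_mosaic)
from tvdizone.rf import assemble_samples, dependence_curve, fit_rf

OUT_IMP = "results/07_rf_importance.csv"
OUT_PDP = "results/07_pdp_precip.csv"


def planted(n=2000, seed=1):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "precip": rng.uniform(0, 1500, n), "temp": rng.normal(2, 4, n),
        "elevation": rng.uniform(3000, 5500, n), "slope": rng.uniform(0, 35, n),
        "aspect": rng.uniform(0, 360, n), "dist_built": rng.uniform(0, 8000, n),
        "dist_water": rng.uniform(0, 8000, n), "landuse": rng.integers(0, 6, n),
        "zone": np.ones(n, dtype=int),
    })
    p01 = (df["precip"] - df["precip"].min()) / np.ptp(df["precip"].to_numpy())
    t01 = (df["temp"] - df["temp"].min()) / np.ptp(df["temp"].to_numpy())
    df["tvdi"] = 0.2 + 0.5 * p01 + 0.2 * t01 + rng.normal(0, 0.02, n)
    return df


def main() -> None:
    scene_cfg = SceneConfig(seed=1)
    scene = generate_scene(scene_cfg)
    cfg = PipelineConfig(scene=scene_cfg)
    annual = []
    for yi in range(len(scene_cfg.years)):
        n, l = annual_composites(scene, yi)
        annual.append(tvdi_mosaic(n, l, scene.zone_map,
                                  fit_zone_edges(n, l, scene.zone_map, cfg)))
    mean_tvdi = annual[0].like(np.nanmean(np.stack([g.data for g in annual]), axis=0))
    factors = {
        "precip": scene.raster(scene.precip.mean(axis=0), "mm"),
        "temp": scene.raster(scene.temp.mean(axis=0), "degC"),
        "elevation": scene.elevation, "slope": scene.slope,
        "aspect": scene.aspect, "dist_built": scene.dist_built,
        "dist_water": scene.dist_water, "landuse": scene.landuse,
    }
    samples = assemble_samples(factors, mean_tvdi, scene.zone_map, cell=4)
    scene_report = fit_rf(samples, seed=1, n_trees=300)
    print("study scene (no planted factor effect on mean TVDI):")
    print(scene_report.importance.round(4))
    print(f"holdout R2 = {scene_report.holdout_r2:.3f} "
          "(near zero: mean TVDI is spatially unstructured by design)\n")

    table = planted()
    report = fit_rf(table, seed=1, n_trees=300)
    print("planted-driver table (precip dominant, temp secondary):")
    print(report.importance.round(4))
    print(f"holdout R2 = {report.holdout_r2:.3f}")
    combined = pd.concat({"scene": scene_report.importance,
                          "planted": report.importance}, axis=1)
    combined.to_csv(OUT_IMP)
    curve = dependence_curve(report, table, "precip", 25)
    curve.as_frame().to_csv(OUT_PDP, index=False)
    print("\npartial dependence on precipitation rises "
          f"{curve.mean_prediction[-1] - curve.mean_prediction[0]:+.3f} "
          "TVDI across the observed range")


if __name__ == "__main__":
    main()
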