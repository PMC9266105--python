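#!/usr/bin/env python
"""Attribute TVDI variability to climate drivers pixel by pixel.

Runs the partial/multiple-correlation driver zoning on three scenes: one
where wetness is coupled to precipitation anomalies only, one coupled to
temperature only, and the default scene with no climate coupling.  The
planted-driver scenes should classify overwhelmingly into the matching
class; the uncoupled scene should fall almost entirely into "other drive
types" (the t/F tests firing only at their false-positive rates).
"""

import numpy as np
import pandas as pd

from tvdizone import SceneConfig, generate_scene
from tvdizone.drivers import driver_zoning_grid
from tvdizone.pipeline import (PipelineConfig, annual_composites,
                               fit_zone_edges, tvdi_mosaic)

OUT = "results/05_driver_area_percent.csv"


def scene_area(coupling_p: float, coupling_t: float, seed: int) -> pd.Series:
    cfg = SceneConfig(grid_rows=60, grid_cols=60, n_zones=4,
                      years=tuple(range(2000, 2018)), seasons=("annual",),
                      wetness_precip_coupling=coupling_p,
                      wetness_temp_coupling=coupling_t,
                      wetness_noise_sd=0.05, wetness_tail=0.0,
                      moisture_trend_per_zone=(0.0,) * 4, seed=seed)
    scene = generate_scene(cfg)
    pc = PipelineConfig(scene=cfg)
    stack = []
    for yi in range(len(cfg.years)):
        n, l = annual_composites(scene, yi)
        stack.append(tvdi_mosaic(n, l, scene.zone_map,
                                 fit_zone_edges(n, l, scene.zone_map, pc)).data)
    res = driver_zoning_grid(np.stack(stack), scene.precip, scene.temp,
                             scene.zone_map.like(stack[0]))
    return res.area_percent["percent"]


def main() -> None:
    table = pd.DataFrame({
        "precip_coupled_scene": scene_area(0.5, 0.0, seed=1),
        "temp_coupled_scene": scene_area(0.0, 0.5, seed=1),
        "uncoupled_scene": scene_area(0.0, 0.0, seed=1),
    })
    table.to_csv(OUT)
    print(table.round(2))
    print("\nplanted drivers dominate their scenes; with no coupling the"
          " F-test leaves almost everything in 'other drive types'.")


if __name__ == "__main__":
    main()
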