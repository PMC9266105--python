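import numpy as np
import pandas as pd
import pytest

from tvdizone import SceneConfig, generate_scene


def planted_table(n=1500, seed=0, effect="precip", secondary=None,
                  secondary_weight=0.2):
    """Factor sample table whose response depends on one dominant factor
    (optionally plus a weaker secondary factor); all others are pure noise."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "precip": rng.uniform(0, 1500, n),
        "temp": rng.normal(2, 4, n),
        "elevation": rng.uniform(3000, 5500, n),
        "slope": rng.uniform(0, 35, n),
        "aspect": rng.uniform(0, 360, n),
        "dist_built": rng.uniform(0, 8000, n),
        "dist_water": rng.uniform(0, 8000, n),
        "landuse": rng.integers(0, 6, n),
        "zone": np.ones(n, dtype=int),
    })
    x = df[effect].to_numpy()
    x01 = (x - x.min()) / np.ptp(x)
    response = 0.2 + 0.6 * x01
    if secondary is not None:
        s = df[secondary].to_numpy()
        s01 = (s - s.min()) / np.ptp(s)
        response = response + secondary_weight * s01
    df["tvdi"] = response + rng.normal(0, 0.02, n)
    return df


@pytest.fixture(scope="session")
def noiseless_scene():
    """Two-zone single-date scene with zero LST noise and uniform NDVI.

    Uniform NDVI keeps every 0.01 feature-space bin populated, so the latent
    dry/wet extremes are observable in each bin and edge fits are exact.
    """
    cfg = SceneConfig(
        grid_rows=300, grid_cols=200, n_zones=2,
        years=(2000,), seasons=("annual",),
        noise_sd_lst=0.0,
        ndvi_beta_params=((1.0, 1.0), (1.0, 1.0)),
        moisture_trend_per_zone=(0.0, 0.0),
        seed=3,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene():
    """Default-structure scene at modest size for end-to-end checks."""
    cfg = SceneConfig(
        grid_rows=60, grid_cols=60, n_zones=4,
        years=tuple(range(2000, 2012)),
        ndvi_beta_params=tuple((1.5, 1.5) for _ in range(4)),
        moisture_trend_per_zone=(-0.006, -0.006, 0.006, 0.006),
        seed=11,
    )
    return generate_scene(cfg)
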