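import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrproton as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tissues():
    return mp.load_tissues()


@pytest.fixture(scope="session")
def elements():
    return mp.load_elements()


@pytest.fixture(scope="session")
def small_scene(tissues):
    """A small two-insert cylinder for fast geometry/extraction tests."""
    cfg = mp.PhantomSceneConfig(
        container_radius=40.0,
        container_height=60.0,
        insert_dims=(24.0, 24.0, 30.0),
        voxel_spacing=(1.0, 1.0, 1.0),
        inserts=(("Muscle", (-15.0, 0.0)), ("Adipose", (15.0, 0.0))),
        sequences=("T1-D-P-W", "T1-D-P-F", "T2-STIR"),
        seed=3,
    )
    return cfg, mp.build_scene(cfg, tissues)


@pytest.fixture(scope="session")
def small_channels(small_scene, tissues):
    """Noiseless normalized channel stack for the small scene."""
    cfg, labels = small_scene
    wmask = mp.water_mask(labels)
    imgs = []
    for i, seq in enumerate(cfg.sequences):
        raw = mp.render_sequence(
            labels, mp.DEFAULT_SIGNAL_TABLE, seq, seed=cfg.seed + i, noise=False
        )
        imgs.append(mp.normalize_by_water(raw, wmask))
    return imgs


def per_tissue_mape(pred: np.ndarray, table, quantity: str) -> dict[str, float]:
    """Per-phantom MAPE (%) of predictions aligned with a voxel table."""
    ref = table.target(quantity)
    out = {}
    for name in np.unique(table.tissue):
        sel = table.tissue == name
        out[str(name)] = float(
            np.mean(np.abs(pred[sel] - ref[sel]) / ref[sel]) * 100.0
        )
    return out
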