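import numpy as np
import pytest

import stainquant as sq


@pytest.fixture(scope="session")
def basis() -> sq.StainBasis:
    """Default adipogenic stain basis (Oil Red O vs hematoxylin)."""
    return sq.lineage_basis("adipogenic")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_scene() -> sq.SyntheticScene:
    """Two disjoint blobs (10% stain 1, 20% stain 2), flat illumination, no noise."""
    return sq.SyntheticScene(
        height=96,
        width=96,
        regions=[sq.Blob(2, 0.7, 0.20, avoid_other=False), sq.Blob(1, 1.0, 0.10)],
        seed=7,
    )


@pytest.fixture()
def shaded_scene() -> sq.SyntheticScene:
    """Same content under a 0.7-corner vignette with dark level and hot pixels."""
    scene = sq.SyntheticScene(
        height=96,
        width=96,
        regions=[sq.Blob(2, 0.7, 0.20, avoid_other=False), sq.Blob(1, 1.0, 0.10)],
        vignette_corner_gain=0.7,
        illumination_scale=0.73,
        dark_level=8.0,
        hot_pixels=[(3, 5, 60.0), (50, 50, 60.0), (90, 10, 60.0)],
        seed=7,
    )
    return scene


@pytest.fixture()
def study_tree(tmp_path):
    """Small rendered 2-donor study (2 x 2 x 3 x 4 = 48 images) with truth tables."""
    root = tmp_path / "study"
    info = sq.generate_synthetic_study(
        root,
        n_donors=2,
        effect_multipliers=[4.0, 1.0],
        seed=11,
        image_size=(64, 64),
    )
    return info
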