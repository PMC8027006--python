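import math

import numpy as np
import pytest

from spinalign.network import ModelConfig, build_model
from spinalign.phantom import PhantomSpec, generate_phantom, sample_spec
from spinalign.schema import LandmarkID as L
from spinalign.schema import LandmarkSet

TINY = ModelConfig(
    input_size=(216, 120),
    n_residual_blocks=12,
    base_channels=8,
    heatmap_downsample=4,
    stage2_refinement_depth=1,
)

MICRO = ModelConfig(
    input_size=(64, 32),
    n_residual_blocks=9,
    base_channels=4,
    heatmap_downsample=4,
    stage2_refinement_depth=1,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return TINY


@pytest.fixture(scope="session")
def micro_model():
    """A very small but complete two-stage model for structural tests."""
    return build_model(MICRO, seed=42)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic mid-size phantom (image, landmarks)."""
    return generate_phantom(PhantomSpec(seed=3, canvas=(432, 240), pixel_spacing=1.0))


@pytest.fixture(scope="session")
def random_landmark_sets():
    """A pool of valid landmark sets spanning the pathology classes."""
    sets = []
    for i in range(24):
        spec = sample_spec(
            100 + i, ["none", "scoliosis", "kyphosis", "implant"][i % 4],
            canvas=(432, 240), pixel_spacing=1.0,
        )
        sets.append(generate_phantom(spec)[1])
    return sets


def build_canonical(spacing: float = 0.5, **overrides) -> LandmarkSet:
    """A hand-constructed configuration with every endplate horizontal and
    the spine, plumb lines and hip axis all on one vertical line.

    All shape angles and slopes are zero by construction; offsets are
    controlled by the x-coordinates (anterior = +x).  ``overrides`` replace
    individual landmark coordinates by name.
    """
    x = 250.0
    pts = {}
    # vertebral centres: straight vertical stack, C2 at the top
    levels = (
        [f"C{i}" for i in range(2, 8)]
        + [f"T{i}" for i in range(1, 13)]
        + [f"L{i}" for i in range(1, 6)]
    )
    for k, lvl in enumerate(levels):
        pts[L[f"CENTER_{lvl}"]] = (x, 120.0 + 26.0 * k)

    def endplate(y):  # (anterior, posterior) with a 40 px horizontal plate
        return (x + 20.0, y), (x - 20.0, y)

    pts[L.C2_DENS_CENTER] = (x, 95.0)
    a, p = endplate(133.0)
    pts[L.C2_ANTEROINFERIOR], pts[L.C2_POSTEROINFERIOR] = a, p
    a, p = endplate(263.0)
    pts[L.C7_ANTEROINFERIOR], pts[L.C7_POSTEROINFERIOR] = a, p
    pts[L.C7_POSTEROSUPERIOR] = (x - 10.0, 237.0)
    a, p = endplate(263.0 + 13.0)
    pts[L.T1_ANTEROSUPERIOR], pts[L.T1_POSTEROSUPERIOR] = a, p
    a, p = endplate(120.0 + 26.0 * 10 - 13.0)
    pts[L.T5_ANTEROSUPERIOR], pts[L.T5_POSTEROSUPERIOR] = a, p
    a, p = endplate(120.0 + 26.0 * 10 + 13.0)
    pts[L.T5_ANTEROINFERIOR], pts[L.T5_POSTEROINFERIOR] = a, p
    a, p = endplate(120.0 + 26.0 * 17 + 13.0)
    pts[L.T12_ANTEROINFERIOR], pts[L.T12_POSTEROINFERIOR] = a, p
    a, p = endplate(120.0 + 26.0 * 18 - 9.0)  # disc gap below T12
    pts[L.L1_ANTEROSUPERIOR], pts[L.L1_POSTEROSUPERIOR] = a, p
    a, p = endplate(120.0 + 26.0 * 21 - 13.0)
    pts[L.L4_ANTEROSUPERIOR], pts[L.L4_POSTEROSUPERIOR] = a, p
    pts[L.S1_ANTERIOR_EDGE] = (x + 20.0, 730.0)
    pts[L.S1_POSTERIOR_EDGE] = (x - 20.0, 730.0)
    pts[L.FEMORAL_HEAD_LEFT_CENTER] = (x + 6.0, 800.0)
    pts[L.FEMORAL_HEAD_RIGHT_CENTER] = (x - 6.0, 800.0)
    for name, xy in overrides.items():
        pts[L[name]] = xy
    return LandmarkSet(pts, pixel_spacing=spacing, image_size=(1000, 500))


def translate_landmarks(lm: LandmarkSet, dx: float, dy: float, big: int = 6000) -> LandmarkSet:
    """Translate all points, re-hosted on a large canvas so image-bound
    validation cannot bind."""
    xy = lm.as_array() + np.array([dx + big / 3, dy + big / 3])
    return LandmarkSet.from_array(xy, lm.pixel_spacing, (big, big), lm.anterior_direction)


def rotate_landmarks(lm: LandmarkSet, theta_deg: float, big: int = 6000) -> LandmarkSet:
    """Rigidly rotate all points about their centroid, re-hosted on a large
    canvas so bounds checks cannot bind."""
    xy = lm.as_array()
    c = xy.mean(axis=0)
    t = math.radians(theta_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    new = (xy - c) @ rot.T + c + (big / 2 - c)
    return LandmarkSet.from_array(
        new, lm.pixel_spacing, (big, big), lm.anterior_direction
    )
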