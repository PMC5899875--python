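import numpy as np
import pytest

from cryoreg.blockmatch import AffineTransform
from cryoreg.phantom import PhantomSpec, make_phantom_pair
from cryoreg.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def smooth_volume():
    """A small band-limited scalar volume in byte range."""
    n = (24, 20, 16)
    x, y, z = np.meshgrid(*[np.linspace(0, 1, k) for k in n], indexing="ij")
    data = 120 + 60 * np.sin(2 * np.pi * x) * np.cos(2 * np.pi * y) + 40 * z
    return Volume(data, (0.2, 0.2, 0.2))


@pytest.fixture(scope="session")
def affine_pair():
    """Phantom pair under a pure affine truth with a multimodal-style remap."""
    spec = PhantomSpec(seed=11, shape=(64, 48, 48), spacing=0.25, rotation_deg=6,
                       scale=(0.96, 1.04, 1.0), translation_mm=(1.5, -1.0, 0.5),
                       intensity_remap="monotone", noise_sd=2.0)
    return make_phantom_pair(spec)


@pytest.fixture(scope="session")
def warp_pair():
    """Phantom pair under a smooth nonrigid truth (identity affine)."""
    spec = PhantomSpec(seed=21, shape=(48, 32, 32), spacing=0.4,
                       warp_amplitude_vox=4, warp_scale_vox=14,
                       intensity_remap="monotone", noise_sd=2.0)
    return make_phantom_pair(spec)


def landmark_error_mm(pair, affine: AffineTransform | None, ffd=None) -> float:
    """Mean error of recovered maps against the pair's paired landmarks."""
    pts = pair.landmarks_ref.points.copy()
    if ffd is not None:
        pts = ffd.map_points(pts)
    if affine is not None:
        pts = affine.apply(pts)
    return float(np.linalg.norm(pts - pair.landmarks_mov.points, axis=1).mean())
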