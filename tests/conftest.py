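import numpy as np
import pytest

from infiltra.io_formats import ImageStack
from infiltra.synthetic import ExponentialLaw, FlatLaw, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(
    planes: np.ndarray,
    pixel_size_um: float = 1.0,
    z_step_um: float | None = None,
    roles: dict | None = None,
) -> ImageStack:
    """Wrap a (z, y, x) or (z, y, x, c) array as a calibrated single-role stack."""
    arr = np.asarray(planes, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., np.newaxis]
    if roles is None:
        roles = {i: ("cell_signal" if i == 0 else "other") for i in range(arr.shape[3])}
    return ImageStack(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        channel_roles=roles,
        source_id="test",
    )


@pytest.fixture
def small_exp_spec():
    """Small, fast section with an exponential infiltration gradient."""
    return SyntheticSpec(
        image_shape_px=(256, 256),
        pixel_size_um=2.0,
        tumor_radius_um=220.0,
        capsule_width_um=100.0,
        law=ExponentialLaw(amplitude_per_mm2=1500.0, decay_per_um=0.01),
        background_mean=10.0,
        background_sd=3.0,
        seed=42,
    )


@pytest.fixture
def small_flat_spec():
    return SyntheticSpec(
        image_shape_px=(256, 256),
        pixel_size_um=2.0,
        tumor_radius_um=220.0,
        capsule_width_um=100.0,
        law=FlatLaw(density_per_mm2=400.0),
        background_mean=10.0,
        background_sd=3.0,
        seed=43,
    )
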