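"""Shared fixtures: small phantom cases generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rgmcmp.phantom import PhantomParams, generate_case

SMALL = dict(grid_shape=(48, 48, 24), spacing_mm=(4.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Phantom parameters on the reduced desk-scale lattice."""
    return PhantomParams(**SMALL)


@pytest.fixture(scope="session")
def default_case(small_params):
    """One paired-course case with the default inter-course change."""
    return generate_case(small_params, seed=0)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free case with a pure 4 mm x-translation between courses."""
    p = PhantomParams(
        rigid_offset_mm=(4.0, 0.0, 0.0),
        rigid_rotation_deg=(0.0, 0.0, 0.0),
        deform_amplitude_mm=0.0,
        noise_sd_hu=0.0,
        **SMALL,
    )
    return generate_case(p, seed=2)


@pytest.fixture(scope="session")
def rotated_case():
    """Noise-free case rotated 5° about the axial axis."""
    p = PhantomParams(
        rigid_offset_mm=(0.0, 0.0, 0.0),
        rigid_rotation_deg=(0.0, 0.0, 5.0),
        deform_amplitude_mm=0.0,
        noise_sd_hu=0.0,
        **SMALL,
    )
    return generate_case(p, seed=3)


@pytest.fixture(scope="session")
def identity_case():
    """Noise-free case with no inter-course change at all."""
    p = PhantomParams(
        rigid_offset_mm=(0.0, 0.0, 0.0),
        rigid_rotation_deg=(0.0, 0.0, 0.0),
        deform_amplitude_mm=0.0,
        noise_sd_hu=0.0,
        **SMALL,
    )
    return generate_case(p, seed=1)


FAST_REG = dict(
    max_iterations=150,
    pyramid_levels=4,
    grid_spacing_voxels=6,
    bspline_iterations=30,
    bspline_sampling_fraction=0.25,
    bspline_pyramid_levels=3,
)


@pytest.fixture(scope="session")
def fast_reg_cfg():
    from rgmcmp.registration import RegistrationConfig

    return RegistrationConfig(**FAST_REG)


@pytest.fixture(scope="session")
def clean_case_rigid(clean_case, fast_reg_cfg):
    """Rigid recovery of the known 4 mm translation (computed once)."""
    from rgmcmp.registration import register_rigid

    return register_rigid(clean_case.ct2, clean_case.ct1, fast_reg_cfg)


@pytest.fixture(scope="session")
def rotated_case_rigid(rotated_case, fast_reg_cfg):
    """Rigid recovery of the known 5° rotation (computed once)."""
    from rgmcmp.registration import register_rigid

    return register_rigid(rotated_case.ct2, rotated_case.ct1, fast_reg_cfg)


@pytest.fixture(scope="session")
def default_case_registrations(default_case, fast_reg_cfg):
    """Rigid and deformable transforms for the warped default case."""
    from rgmcmp.registration import register_bspline, register_rigid

    rigid = register_rigid(default_case.ct2, default_case.ct1, fast_reg_cfg)
    deform = register_bspline(default_case.ct2, default_case.ct1, fast_reg_cfg, initial=rigid)
    return rigid, deform


def random_mask(rng: np.random.Generator, shape=(12, 12, 12), p=0.3) -> np.ndarray:
    """Random blobby mask: thresholded smoothed noise, possibly empty."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    return (field > np.quantile(field, 1 - p)).astype(np.uint8)
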