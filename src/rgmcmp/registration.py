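"""Rigid and B-spline registration and contour propagation.

Registers the first-course CT (moving) onto the second-course CT (fixed)
and propagates images/contours onto the fixed lattice, producing the
guidance channels aCT1 and aCTV1. Both stages optimize Mattes mutual
information with regular-step gradient descent (initial step 8, minimum
step 0.001, at most 500 iterations) over a four-level image pyramid; the
deformable stage uses a cubic B-spline transform with a control-point
spacing of 16 voxels at the finest level, preceded by a rigid
pre-alignment, and is materialized as a dense voxel displacement field on
the fixed grid.

Images are resampled with linear interpolation and masks with
nearest-neighbour interpolation, so propagated masks stay strictly binary.
Voxels that map outside the moving image are filled with −1000 HU
(images) or 0 (masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import SimpleITK as sitk

from .core import LabelMask, Volume

__all__ = [
    "RegistrationConfig",
    "SpatialTransform",
    "RegistrationError",
    "register_rigid",
    "register_bspline",
    "propagate",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    metric: str = "mutual_information"
    optimizer_initial_step: float = 8.0
    max_iterations: int = 500
    min_step: float = 0.001
    pyramid_levels: int = 4
    grid_spacing_voxels: int = 16
    mi_bins: int = 32
    sampling_fraction: float = 0.25
    sampling_seed: int = 20240313
    # deformable stage: L-BFGS iterations per pyramid level, its
    # (deterministic, regular-grid) metric sampling fraction, and an
    # optional pyramid depth of its own (defaults to pyramid_levels)
    bspline_iterations: int = 30
    bspline_sampling_fraction: float = 0.25
    bspline_pyramid_levels: int | None = None

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be ≥ 1")
        if self.grid_spacing_voxels < 2:
            raise ValueError("grid_spacing_voxels must be ≥ 2")


@dataclass
class SpatialTransform:
    """A rigid transform (6 parameters) or a dense displacement field.

    ``rigid_params`` is (rot_x, rot_y, rot_z) in radians followed by the
    translation (mm); ``center_mm`` is the rotation centre. ``dvf`` maps
    each fixed-grid voxel's physical point to its corresponding
    moving-image point: moving = fixed + dvf, components in mm along the
    grid axes, array shape (X, Y, Z, 3).
    """

    kind: str  # "rigid" | "bspline"
    fixed_shape: tuple[int, int, int]
    fixed_spacing: tuple[float, float, float]
    rigid_params: Optional[tuple[float, ...]] = None
    center_mm: Optional[tuple[float, float, float]] = None
    dvf: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def identity_rigid(cls, shape, spacing) -> "SpatialTransform":
        center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls("rigid", tuple(shape), tuple(spacing), rigid_params=(0.0,) * 6, center_mm=center)

    @classmethod
    def dense(cls, dvf: np.ndarray, fixed_shape, fixed_spacing, metadata=None) -> "SpatialTransform":
        dvf = np.asarray(dvf, dtype=np.float64)
        if dvf.shape != (*fixed_shape, 3):
            raise ValueError(f"dvf shape {dvf.shape} does not match grid {fixed_shape}")
        if not np.all(np.isfinite(dvf)):
            raise ValueError("dvf must be finite everywhere")
        return cls(
            "bspline", tuple(fixed_shape), tuple(fixed_spacing), dvf=dvf, metadata=metadata or {}
        )

    def to_sitk(self) -> sitk.Transform:
        if self.kind == "rigid":
            t = sitk.Euler3DTransform()
            t.SetCenter(self.center_mm)
            t.SetParameters(self.rigid_params)
            return t
        field_img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.dvf.transpose(2, 1, 0, 3)), isVector=True
        )
        field_img.SetSpacing(self.fixed_spacing)
        return sitk.DisplacementFieldTransform(field_img)

    @property
    def translation_mm(self) -> np.ndarray:
        if self.kind != "rigid":
            raise ValueError("translation is defined for rigid transforms only")
        return np.asarray(self.rigid_params[3:])

    @property
    def rotation_deg(self) -> np.ndarray:
        if self.kind != "rigid":
            raise ValueError("rotation is defined for rigid transforms only")
        return np.rad2deg(self.rigid_params[:3])

    def mean_displacement_mm(self) -> float:
        """Mean displacement magnitude over the fixed grid."""
        if self.kind == "rigid":
            d = densify(self).dvf
        else:
            d = self.dvf
        return float(np.sqrt((d**2).sum(axis=-1)).mean())


def _check_inputs(fixed: Volume, moving: Volume) -> None:
    for v, name in ((fixed, "fixed"), (moving, "moving")):
        if np.ptp(v.array) == 0:
            raise RegistrationError(
                f"{name} image has constant intensity: the similarity metric is "
                "undefined and the optimization cannot converge"
            )


def _pyramid(cfg: RegistrationConfig, shape) -> tuple[list[int], list[float]]:
    shrink, sigmas = [], []
    min_dim = min(shape)
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        f = 2**level
        while f > 1 and min_dim // f < 4:
            f //= 2
        shrink.append(f)
        sigmas.append(f / 2.0 if f > 1 else 0.0)
    return shrink, sigmas


def _base_method(cfg: RegistrationConfig, shape) -> sitk.ImageRegistrationMethod:
    rm = sitk.ImageRegistrationMethod()
    rm.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.mi_bins)
    rm.SetMetricSamplingStrategy(rm.RANDOM)
    rm.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.sampling_seed)
    rm.SetInterpolator(sitk.sitkLinear)
    rm.SetOptimizerAsRegularStepGradientDescent(
        learningRate=cfg.optimizer_initial_step,
        minStep=cfg.min_step,
        numberOfIterations=cfg.max_iterations,
    )
    rm.SetOptimizerScalesFromPhysicalShift()
    shrink, sigmas = _pyramid(cfg, shape)
    rm.SetShrinkFactorsPerLevel(shrink)
    rm.SetSmoothingSigmasPerLevel(sigmas)
    return rm


def _run(rm, fixed_img, moving_img) -> sitk.Transform:
    try:
        return rm.Execute(fixed_img, moving_img)
    except RuntimeError as e:  # pragma: no cover - ITK error text varies
        raise RegistrationError(f"registration failed to converge: {e}") from e


def register_rigid(
    fixed: Volume, moving: Volume, cfg: RegistrationConfig | None = None
) -> SpatialTransform:
    """6-DOF rigid alignment of ``moving`` onto ``fixed``."""
    cfg = cfg or RegistrationConfig()
    _check_inputs(fixed, moving)
    fimg, mimg = fixed.to_sitk(), moving.to_sitk()
    rm = _base_method(cfg, fixed.shape)
    init = sitk.CenteredTransformInitializer(
        fimg, mimg, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    rm.SetInitialTransform(init, inPlace=True)
    result = _run(rm, fimg, mimg)
    euler = sitk.Euler3DTransform(result)
    return SpatialTransform(
        kind="rigid",
        fixed_shape=fixed.shape,
        fixed_spacing=fixed.spacing,
        rigid_params=tuple(euler.GetParameters()),
        center_mm=tuple(euler.GetCenter()),
        metadata={
            "metric": cfg.metric,
            "pyramid_levels": cfg.pyramid_levels,
            "stop_condition": rm.GetOptimizerStopConditionDescription(),
            "final_metric": rm.GetMetricValue(),
        },
    )


def register_bspline(
    fixed: Volume,
    moving: Volume,
    cfg: RegistrationConfig | None = None,
    initial: SpatialTransform | None = None,
) -> SpatialTransform:
    """Deformable B-spline alignment, returned as a dense DVF on the fixed grid.

    A rigid pre-alignment is run first (or taken from ``initial``); the
    B-spline stage then refines it and the composite map is voxelized.
    """
    cfg = cfg or RegistrationConfig()
    _check_inputs(fixed, moving)
    rigid = initial if initial is not None else register_rigid(fixed, moving, cfg)
    fimg, mimg = fixed.to_sitk(), moving.to_sitk()

    # coarse-to-fine coefficient refinement: the control-point mesh starts at
    # 1/2^(L-1) of the final density and doubles at every pyramid level, so
    # the finest level reaches the configured control-point spacing
    levels = cfg.bspline_pyramid_levels or cfg.pyramid_levels
    mesh_coarse = [
        max(1, int(round(n / cfg.grid_spacing_voxels / 2 ** (levels - 1))))
        for n in fixed.shape
    ]
    mesh_fine = [m * 2 ** (levels - 1) for m in mesh_coarse]
    bspline = sitk.BSplineTransformInitializer(fimg, mesh_coarse, order=3)

    rm = sitk.ImageRegistrationMethod()
    # mean squares for the deformable stage: both courses are CT, and an
    # unregularized B-spline driven by MI is free to trade anatomical
    # correspondence for histogram compaction (see docs/methods.md)
    rm.SetMetricAsMeanSquares()
    rm.SetMetricSamplingStrategy(rm.REGULAR)
    rm.SetMetricSamplingPercentage(cfg.bspline_sampling_fraction, cfg.sampling_seed)
    rm.SetInterpolator(sitk.sitkLinear)
    # L-BFGS for the coefficient optimization: the regular-step rule of the
    # rigid stage takes metric-scaled steps far too large for a dense
    # coefficient space
    rm.SetOptimizerAsLBFGS2(numberOfIterations=cfg.bspline_iterations)
    shrink, sigmas = _pyramid(
        RegistrationConfig(**{**cfg.__dict__, "pyramid_levels": levels}), fixed.shape
    )
    rm.SetShrinkFactorsPerLevel(shrink)
    rm.SetSmoothingSigmasPerLevel(sigmas)
    rm.SetMovingInitialTransform(rigid.to_sitk())
    rm.SetInitialTransformAsBSpline(
        bspline, inPlace=True, scaleFactors=[2**i for i in range(levels)]
    )
    result = _run(rm, fimg, mimg)

    composite = sitk.CompositeTransform(3)
    composite.AddTransform(rigid.to_sitk())
    composite.AddTransform(result)

    dvf_filter = sitk.TransformToDisplacementFieldFilter()
    dvf_filter.SetReferenceImage(fimg)
    field = dvf_filter.Execute(composite)
    dvf = sitk.GetArrayFromImage(field).transpose(2, 1, 0, 3)
    return SpatialTransform.dense(
        dvf=dvf,
        fixed_shape=fixed.shape,
        fixed_spacing=fixed.spacing,
        metadata={
            "metric": cfg.metric,
            "pyramid_levels": cfg.pyramid_levels,
            "grid_spacing_voxels": cfg.grid_spacing_voxels,
            "mesh_size": mesh_fine,
            "stop_condition": rm.GetOptimizerStopConditionDescription(),
            "final_metric": rm.GetMetricValue(),
        },
    )


def densify(t: SpatialTransform) -> SpatialTransform:
    """Materialize any transform as a dense DVF on its fixed grid."""
    if t.kind == "bspline":
        return t
    ref = Volume(
        np.zeros(t.fixed_shape, dtype=np.float32), t.fixed_spacing
    ).to_sitk()
    dvf_filter = sitk.TransformToDisplacementFieldFilter()
    dvf_filter.SetReferenceImage(ref)
    field = dvf_filter.Execute(t.to_sitk())
    dvf = sitk.GetArrayFromImage(field).transpose(2, 1, 0, 3)
    return SpatialTransform.dense(dvf, t.fixed_shape, t.fixed_spacing, metadata=dict(t.metadata))


def propagate(
    image_or_mask: Volume | LabelMask,
    t: SpatialTransform,
    target_grid: Volume | tuple | None = None,
) -> Volume | LabelMask:
    """Resample an image (linear) or mask (nearest-neighbour) through ``t``
    onto the fixed grid."""
    if target_grid is None:
        shape, spacing = t.fixed_shape, t.fixed_spacing
    elif isinstance(target_grid, Volume):
        shape, spacing = target_grid.shape, target_grid.spacing
    else:
        shape, spacing = target_grid

    is_mask = isinstance(image_or_mask, LabelMask)
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    fill = 0.0 if is_mask else -1000.0

    ref = Volume(np.zeros(shape, dtype=np.float32), spacing).to_sitk()
    out_img = sitk.Resample(image_or_mask.to_sitk(), ref, t.to_sitk(), interp, fill)
    arr = sitk.GetArrayFromImage(out_img).transpose(2, 1, 0)
    if is_mask:
        return LabelMask((arr > 0.5).astype(np.uint8), spacing)
    return Volume(arr.astype(np.float32), spacing)
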