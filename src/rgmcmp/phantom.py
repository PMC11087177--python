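"""Synthetic paired-course pelvic phantom.

Each case emulates the two-course structure of an adaptive-radiotherapy
dataset: a course-1 CT with its target mask (CT1/CTV1) and a course-2 pair
(CT2/CTV2) related to course 1 by a known rigid offset composed with a
smooth random warp, re-rendered with independent voxel noise.

The anatomy is analytic — an elliptic soft-tissue body cylinder (~0 HU) on
air (−1000 HU), an ellipsoidal target (+80 HU by default, a CTV surrogate),
two bone-surrogate rods (+700 HU) and a smooth low-frequency soft-tissue
texture that gives the registration metric gradient structure. Course 2 is
rendered by evaluating the same analytic anatomy at rigidly-then-smoothly
warped coordinates, so the inter-course transform is known exactly and is
stored with the case as a dense displacement field on the course-2 grid.

The smooth warp is a low-resolution random vector lattice upsampled by
cubic-spline interpolation, rescaled so the maximum displacement equals
``deform_amplitude_mm`` and capped below half the correlation length so
the map stays invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import LabelMask, Volume

__all__ = ["PhantomParams", "PatientCase", "generate_case", "generate_cohort", "save_case"]


class PhantomError(ValueError):
    """The requested phantom cannot be generated (e.g. target leaves the grid)."""


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (96, 80, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    body_radius_frac: float = 0.44
    target_radii_mm: tuple[float, float, float] = (24.0, 20.0, 32.0)
    margin_mm: float = 10.0  # CTV = visible lesion + this (invisible) margin
    target_center_mm: tuple[float, float, float] = (0.0, -6.0, 0.0)
    rigid_offset_mm: tuple[float, float, float] = (4.0, 4.0, 1.5)
    rigid_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 3.0)
    deform_amplitude_mm: float = 20.0
    deform_scale_mm: float = 60.0
    noise_sd_hu: float = 12.0
    organ_contrast_hu: dict = field(
        default_factory=lambda: {"air": -1000.0, "body": 0.0, "target": 80.0, "bone": 700.0}
    )
    texture_amplitude_hu: float = 40.0
    hu_window: tuple[float, float] = (-1000.0, 1500.0)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.target_radii_mm):
            raise PhantomError("target radii must be strictly positive")
        if self.margin_mm < 0 or any(r - self.margin_mm < 2.0 for r in self.target_radii_mm):
            raise PhantomError(
                "margin_mm must be nonnegative and leave a visible lesion core "
                "of at least 2 mm inside the CTV"
            )
        if self.deform_scale_mm <= 0 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("scales and spacings must be strictly positive")
        if self.deform_amplitude_mm < 0:
            raise PhantomError("deform_amplitude_mm must be nonnegative")
        if not (0 < self.body_radius_frac <= 0.5):
            raise PhantomError("body_radius_frac must lie in (0, 0.5]")
        ext = self.extent_mm
        # 0.90: the narrowest cross-section of the tapered body cylinder
        rx = self.body_radius_frac * ext[0] * 0.90
        ry = self.body_radius_frac * ext[1] * 0.90
        cx, cy, _ = self.target_center_mm
        tx, ty, _ = self.target_radii_mm
        # worst-case rigid+warp displacement of the target boundary
        slack = float(np.linalg.norm(self.rigid_offset_mm)) + self.deform_amplitude_mm
        if (abs(cx) + tx + slack) >= rx or (abs(cy) + ty + slack) >= ry:
            raise PhantomError(
                "target ellipsoid does not fit inside the body cylinder at both courses"
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing_mm))


@dataclass
class PatientCase:
    case_id: str
    ct1: Volume
    ctv1: LabelMask
    ct2: Volume
    ctv2: LabelMask
    true_transform: "object"  # SpatialTransform (dense DVF); set by generate_case
    params: PhantomParams | None = None
    seed: int | None = None


# -- analytic anatomy --------------------------------------------------------

class _Anatomy:
    """Analytic phantom evaluated at arbitrary physical coordinates (mm,
    centred at the volume midpoint)."""

    def __init__(self, params: PhantomParams, rng: np.random.Generator):
        self.p = params
        ext = params.extent_mm
        self.body_r = (params.body_radius_frac * ext[0], params.body_radius_frac * ext[1])
        # bone-surrogate rods parallel to the axial direction
        self.rod_centers = (
            (-0.55 * self.body_r[0], 0.35 * self.body_r[1]),
            (0.55 * self.body_r[0], 0.35 * self.body_r[1]),
        )
        self.rod_radius = 8.0
        # mid-contrast organ surrogates around the target: the deformable
        # registration recovers the local warp from their interfaces (as it
        # does from bladder/rectum/bowel on pelvic CT); none of them encodes
        # the CTV's margin extent
        self.organs = [
            ((-45.0, 25.0, -15.0), (14.0, 12.0, 16.0), -120.0),
            ((40.0, 20.0, 10.0), (13.0, 15.0, 14.0), 60.0),
            ((0.0, 38.0, 20.0), (16.0, 12.0, 14.0), -70.0),
            ((-35.0, -30.0, 25.0), (12.0, 12.0, 12.0), 120.0),
            ((38.0, -28.0, -20.0), (12.0, 14.0, 13.0), 100.0),
        ]
        # smooth intensity texture: a fixed bank of random cosine modes
        n_modes = 8
        scale = max(params.deform_scale_mm, 30.0)
        self.tex_k = rng.normal(0.0, 1.0 / scale, size=(n_modes, 3))
        self.tex_phase = rng.uniform(0, 2 * np.pi, size=n_modes)
        self.tex_amp = rng.normal(0.0, 1.0, size=n_modes)
        norm = np.sum(np.abs(self.tex_amp)) or 1.0
        self.tex_amp *= params.texture_amplitude_hu / norm

    def _taper(self, z) -> np.ndarray:
        # mild axial narrowing (a pelvis-like taper) so the image has
        # gradient structure along the slice direction as well
        ext_z = self.p.extent_mm[2]
        return 1.0 - 0.10 * (z / ext_z + 0.5)

    def body(self, x, y, z) -> np.ndarray:
        rx, ry = self.body_r
        t = self._taper(z)
        return (x / (rx * t)) ** 2 + (y / (ry * t)) ** 2 <= 1.0

    def _ellipsoid(self, x, y, z, radii) -> np.ndarray:
        cx, cy, cz = self.p.target_center_mm
        tx, ty, tz = radii
        return ((x - cx) / tx) ** 2 + ((y - cy) / ty) ** 2 + ((z - cz) / tz) ** 2 <= 1.0

    def target(self, x, y, z) -> np.ndarray:
        """The CTV mask: gross lesion plus the suspected-spread margin."""
        return self._ellipsoid(x, y, z, self.p.target_radii_mm)

    def lesion_core(self, x, y, z) -> np.ndarray:
        """The CT-visible gross lesion inside the CTV."""
        radii = tuple(r - self.p.margin_mm for r in self.p.target_radii_mm)
        return self._ellipsoid(x, y, z, radii)

    def hu(self, x, y, z) -> np.ndarray:
        c = self.p.organ_contrast_hu
        out = np.full(x.shape, c["air"], dtype=np.float64)
        body = self.body(x, y, z)
        tex = np.zeros_like(x)
        for k, ph, amp in zip(self.tex_k, self.tex_phase, self.tex_amp):
            tex += amp * np.cos(2 * np.pi * (k[0] * x + k[1] * y + k[2] * z) + ph)
        out[body] = c["body"] + tex[body]
        for (ocx, ocy, ocz), (orx, ory, orz), contrast in self.organs:
            organ = (
                ((x - ocx) / orx) ** 2 + ((y - ocy) / ory) ** 2 + ((z - ocz) / orz) ** 2
                <= 1.0
            ) & body
            out[organ] = c["body"] + contrast + tex[organ]
        # only the gross lesion core carries intensity contrast: the CTV's
        # margin component is isointense with soft tissue, as clinical
        # microscopic spread is — its extent is knowable only from the
        # delineated contour
        tgt = self.lesion_core(x, y, z)
        out[tgt] = c["target"] + tex[tgt]
        # rods are truncated axially: their high-contrast end caps anchor the
        # slice direction for registration, like femoral heads on pelvic CT
        ext_z = self.p.extent_mm[2]
        rod_band = np.abs(z + 0.10 * ext_z) <= 0.30 * ext_z
        for rc in self.rod_centers:
            rod = ((x - rc[0]) ** 2 + (y - rc[1]) ** 2 <= self.rod_radius**2) & body & rod_band
            out[rod] = c["bone"]
        return out


def _grid_coords(params: PhantomParams):
    """Physical voxel-centre coordinates (mm), centred at the volume midpoint."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(params.grid_shape, params.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _smooth_warp(params: PhantomParams, rng: np.random.Generator):
    """Random smooth displacement field (mm) on the course-2 grid."""
    if params.deform_amplitude_mm == 0:
        return [np.zeros(params.grid_shape) for _ in range(3)]
    ext = params.extent_mm
    lat_shape = [max(int(np.ceil(e / params.deform_scale_mm)) + 3, 4) for e in ext]
    lattice = rng.normal(0.0, 1.0, size=(3, *lat_shape))
    # invertibility cap: max displacement < correlation length / 2
    amp = min(params.deform_amplitude_mm, 0.5 * params.deform_scale_mm - 1e-6)
    fields = []
    for c in range(3):
        coords = [
            (np.arange(n) + 0.5) * ls / n - 0.5
            for n, ls in zip(params.grid_shape, lat_shape)
        ]
        mesh = np.meshgrid(*coords, indexing="ij")
        fields.append(
            ndimage.map_coordinates(lattice[c], np.stack(mesh), order=3, mode="nearest")
        )
    u = np.stack(fields)
    mag = np.sqrt((u**2).sum(axis=0)).max()
    if mag > 0:
        u *= amp / mag
    return list(u)


def _rigid_map(params: PhantomParams, x, y, z):
    """Apply the course-2 → course-1 rigid map (rotation about the volume
    centre, then translation)."""
    rx, ry, rz = np.deg2rad(params.rigid_rotation_deg)
    cx, cy, cz = np.cos([rx, ry, rz])
    sx, sy, sz = np.sin([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    t = np.asarray(params.rigid_offset_mm)
    pts = np.stack([x, y, z])
    out = np.tensordot(R, pts, axes=1) + t.reshape(3, 1, 1, 1)
    return out[0], out[1], out[2]


def generate_case(params: PhantomParams, seed: int, case_id: str | None = None) -> PatientCase:
    """Generate one paired-course case; bit-reproducible from (params, seed)."""
    from .registration import SpatialTransform  # local import avoids a cycle

    rng = np.random.default_rng(int(seed))
    anatomy = _Anatomy(params, rng)
    x, y, z = _grid_coords(params)

    # course 1: anatomy on the unwarped grid
    hu1 = anatomy.hu(x, y, z)
    ctv1 = anatomy.target(x, y, z)

    # course 2: anatomy sampled at T(x) = R(x) + u(x)
    ux, uy, uz = _smooth_warp(params, rng)
    wx, wy, wz = _rigid_map(params, x, y, z)
    wx, wy, wz = wx + ux, wy + uy, wz + uz
    hu2 = anatomy.hu(wx, wy, wz)
    ctv2 = anatomy.target(wx, wy, wz)

    if not ctv1.any() or not ctv2.any():
        raise PhantomError("target mask is empty on the generated grid")
    for m, name in ((ctv1, "ctv1"), (ctv2, "ctv2")):
        edges = (
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        )
        if edges:
            raise PhantomError(
                f"{name} touches the grid boundary under the requested transform; "
                "reduce the offset/warp or enlarge the grid"
            )

    lo, hi = params.hu_window
    noise1 = rng.normal(0.0, params.noise_sd_hu, hu1.shape) if params.noise_sd_hu else 0.0
    noise2 = rng.normal(0.0, params.noise_sd_hu, hu2.shape) if params.noise_sd_hu else 0.0
    ct1 = np.clip(hu1 + noise1, lo, hi).astype(np.float32)
    ct2 = np.clip(hu2 + noise2, lo, hi).astype(np.float32)

    spacing = params.spacing_mm
    # displacement (mm) of the course2→course1 map on the course-2 grid
    dvf = np.stack([wx - x, wy - y, wz - z], axis=-1)
    true_t = SpatialTransform.dense(
        dvf=dvf, fixed_shape=params.grid_shape, fixed_spacing=spacing
    )
    cid = case_id or f"case{int(seed):06d}"
    return PatientCase(
        case_id=cid,
        ct1=Volume(ct1, spacing),
        ctv1=LabelMask(ctv1.astype(np.uint8), spacing),
        ct2=Volume(ct2, spacing),
        ctv2=LabelMask(ctv2.astype(np.uint8), spacing),
        true_transform=true_t,
        params=params,
        seed=int(seed),
    )


def _vary_params(params: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-case draw of the inter-course change magnitudes."""
    d = asdict(params)
    d["rigid_offset_mm"] = tuple(rng.uniform(-6.0, 6.0, 2)) + (rng.uniform(-2.0, 2.0),)
    d["rigid_rotation_deg"] = (0.0, 0.0, float(rng.uniform(-5.0, 5.0)))
    d["deform_amplitude_mm"] = float(rng.uniform(16.0, 26.0))
    d["target_radii_mm"] = tuple(
        float(r * rng.uniform(0.90, 1.10)) for r in params.target_radii_mm
    )
    # the suspected-spread margin is a clinical judgement that varies from
    # case to case and has no intensity correlate
    d["margin_mm"] = float(rng.uniform(4.0, 12.0))
    return PhantomParams(**d)


def generate_cohort(
    n_cases: int, params: PhantomParams | None = None, seed: int = 0
) -> list[PatientCase]:
    """Deterministic cohort: per-case seeds derived from the cohort seed by a
    counter; per-case transform magnitudes drawn from fixed ranges."""
    if n_cases < 1:
        raise ValueError("n_cases must be ≥ 1")
    params = params or PhantomParams()
    cases = []
    for i in range(n_cases):
        case_seed = int((seed * 1_000_003 + i) % 2**31)
        vary_rng = np.random.default_rng(case_seed + 17)
        case_params = _vary_params(params, vary_rng)
        cases.append(generate_case(case_params, case_seed, case_id=f"case{i:03d}"))
    return cases


def save_case(case: PatientCase, out_dir: str | Path) -> None:
    """Write the four NIfTI volumes and a JSON sidecar with the transform."""
    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    write_volume(case.ct1, out / f"{cid}_ct1.nii.gz")
    write_volume(case.ctv1, out / f"{cid}_ctv1.nii.gz")
    write_volume(case.ct2, out / f"{cid}_ct2.nii.gz")
    write_volume(case.ctv2, out / f"{cid}_ctv2.nii.gz")
    side = {
        "case_id": cid,
        "seed": case.seed,
        "params": asdict(case.params) if case.params else None,
    }
    (out / f"{cid}_transform.json").write_text(json.dumps(side, indent=2))
    np.save(out / f"{cid}_dvf.npy", case.true_transform.dvf)
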