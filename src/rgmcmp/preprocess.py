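"""Preprocessing chain: axial slab extraction, union-body cropping,
resampling to the training grid, HU truncation and normalization.

The chain runs slab → crop → resample → normalize. The axial slab keeps a
fixed number of slices containing every mask-positive slice, centred on
the mask's axial midpoint when there is slack. The crop is lateral only
(the slab fixes the axial extent): its box is the bounding box of the
union of the body masks of the two images being merged, so both bodies
survive the crop. CT images are resampled with linear interpolation and
masks with nearest-neighbour, so masks stay strictly binary; intensities
are then clipped to the HU window (default −1000 … 1500) and mapped
affinely onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GridError, LabelMask, Volume, require_same_lattice

__all__ = [
    "PreprocessConfig",
    "extract_slab",
    "body_mask",
    "crop_to_union",
    "resample_to_grid",
    "normalize_hu",
    "preprocess_case",
]


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    slab_slices: int = 48
    target_shape: tuple[int, int, int] = (192, 160, 48)
    hu_window: tuple[float, float] = (-1000.0, 1500.0)
    body_threshold_hu: float = -300.0

    def __post_init__(self) -> None:
        if self.target_shape[2] != self.slab_slices:
            raise PreprocessError(
                f"target_shape axial extent {self.target_shape[2]} must equal "
                f"slab_slices {self.slab_slices}"
            )
        if self.hu_window[0] >= self.hu_window[1]:
            raise PreprocessError("hu_window lower bound must be below the upper bound")


def _resize(arr: np.ndarray, shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Resample to an explicit shape; half-pixel-centre convention."""
    coords = np.meshgrid(
        *[
            np.clip((np.arange(so) + 0.5) * si / so - 0.5, 0, si - 1)
            for si, so in zip(arr.shape, shape)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(arr.astype(np.float64), np.stack(coords), order=order, mode="nearest")


def extract_slab(
    ct: Volume, mask: LabelMask, cfg: PreprocessConfig | None = None
) -> tuple[Volume, LabelMask, tuple[int, int]]:
    """Keep ``slab_slices`` contiguous axial slices containing every
    mask-positive slice; returns the slab pair and the (start, stop) range."""
    cfg = cfg or PreprocessConfig()
    require_same_lattice(ct, mask, "ct and mask")
    n_ax = ct.shape[2]
    if n_ax < cfg.slab_slices:
        raise PreprocessError(
            f"volume has {n_ax} axial slices, fewer than the {cfg.slab_slices}-slice slab"
        )
    pos = np.where(mask.array.any(axis=(0, 1)))[0]
    if pos.size == 0:
        raise PreprocessError("mask is empty; slab placement undefined")
    lo, hi = int(pos[0]), int(pos[-1])
    if hi - lo + 1 > cfg.slab_slices:
        raise PreprocessError(
            f"mask spans {hi - lo + 1} axial slices, more than the slab of {cfg.slab_slices}"
        )
    mid = (lo + hi + 1) // 2
    start = mid - cfg.slab_slices // 2
    start = max(0, min(start, n_ax - cfg.slab_slices))  # clamp into the volume
    start = min(start, lo)  # inclusion wins over centring
    start = max(start, hi + 1 - cfg.slab_slices)
    stop = start + cfg.slab_slices
    sl = slice(start, stop)
    return (
        Volume(ct.array[:, :, sl].copy(), ct.spacing),
        LabelMask(mask.array[:, :, sl].copy(), mask.spacing),
        (start, stop),
    )


def body_mask(ct: Volume, cfg: PreprocessConfig | None = None) -> LabelMask:
    """Largest above-threshold connected component, closed and hole-filled."""
    cfg = cfg or PreprocessConfig()
    above = ct.array > cfg.body_threshold_hu
    if not above.any():
        raise PreprocessError(
            f"no voxels above the body threshold {cfg.body_threshold_hu} HU"
        )
    labels, n = ndimage.label(above)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        above = labels == (1 + int(np.argmax(sizes)))
    # closing is kept extensive (it must never remove component voxels, which
    # plain binary_closing does at the grid border)
    closed = ndimage.binary_closing(above, structure=np.ones((3, 3, 3), bool)) | above
    filled = ndimage.binary_fill_holes(closed)
    return LabelMask(filled.astype(np.uint8), ct.spacing)


def crop_to_union(
    ct2: Volume,
    act1: Volume,
    masks: list[LabelMask] | None = None,
    cfg: PreprocessConfig | None = None,
):
    """Crop everything to the lateral bounding box of body(ct2) ∪ body(act1).

    Returns (cropped ct2, cropped act1, cropped masks, box) where box is
    ((x0, x1), (y0, y1)) with half-open bounds.
    """
    cfg = cfg or PreprocessConfig()
    require_same_lattice(ct2, act1, "ct2 and act1")
    union = body_mask(ct2, cfg).array.astype(bool) | body_mask(act1, cfg).array.astype(bool)
    proj_x = np.where(union.any(axis=(1, 2)))[0]
    proj_y = np.where(union.any(axis=(0, 2)))[0]
    box = ((int(proj_x[0]), int(proj_x[-1]) + 1), (int(proj_y[0]), int(proj_y[-1]) + 1))
    (x0, x1), (y0, y1) = box

    def _crop(v):
        arr = v.array[x0:x1, y0:y1, :].copy()
        cls = LabelMask if isinstance(v, LabelMask) else Volume
        return cls(arr, v.spacing)

    cropped_masks = [_crop(m) for m in (masks or [])]
    return _crop(ct2), _crop(act1), cropped_masks, box


def resample_to_grid(
    vol: Volume, mask: LabelMask | None, cfg: PreprocessConfig | None = None
) -> tuple[Volume, LabelMask | None]:
    """Resample to ``target_shape``: image linearly, mask nearest-neighbour."""
    cfg = cfg or PreprocessConfig()
    shape = tuple(cfg.target_shape)
    if any(s < 2 for s in vol.shape):
        raise PreprocessError(f"degenerate input extent {vol.shape}")
    new_spacing = tuple(
        sp * si / so for sp, si, so in zip(vol.spacing, vol.shape, shape)
    )
    out_img = Volume(_resize(vol.array, shape, order=1).astype(np.float32), new_spacing)
    out_mask = None
    if mask is not None:
        out_mask = LabelMask(
            _resize(mask.array, shape, order=0).astype(np.uint8), new_spacing
        )
    return out_img, out_mask


def normalize_hu(vol: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clip to the HU window and map affinely onto [0, 1]."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.hu_window
    arr = (np.clip(vol.array, lo, hi) - lo) / (hi - lo)
    return Volume(arr.astype(np.float32), vol.spacing, vol.origin)


@dataclass
class PreprocessedCase:
    """Network-ready channels for one case plus traceability metadata."""

    act1: Volume  # normalized
    actv1: LabelMask
    ct2: Volume  # normalized
    ctv2: LabelMask
    slab_range: tuple[int, int]
    crop_box: tuple


def preprocess_case(
    act1: Volume,
    actv1: LabelMask,
    ct2: Volume,
    ctv2: LabelMask,
    cfg: PreprocessConfig | None = None,
) -> PreprocessedCase:
    """Full slab → crop → resample → normalize chain on one aligned case.

    The slab is placed from the union of the propagated contour and the
    course-2 contour so both survive; the identical slab and crop box are
    applied to every channel.
    """
    cfg = cfg or PreprocessConfig()
    union_mask = LabelMask(
        (actv1.array.astype(bool) | ctv2.array.astype(bool)).astype(np.uint8),
        actv1.spacing,
    )
    _, _, (start, stop) = extract_slab(ct2, union_mask, cfg)
    sl = slice(start, stop)

    def _slab(v):
        cls = LabelMask if isinstance(v, LabelMask) else Volume
        return cls(v.array[:, :, sl].copy(), v.spacing)

    ct2_s, act1_s = _slab(ct2), _slab(act1)
    actv1_s, ctv2_s = _slab(actv1), _slab(ctv2)

    ct2_c, act1_c, (actv1_c, ctv2_c), box = crop_to_union(
        ct2_s, act1_s, [actv1_s, ctv2_s], cfg
    )
    ct2_r, ctv2_r = resample_to_grid(ct2_c, ctv2_c, cfg)
    act1_r, actv1_r = resample_to_grid(act1_c, actv1_c, cfg)
    return PreprocessedCase(
        act1=normalize_hu(act1_r, cfg),
        actv1=actv1_r,
        ct2=normalize_hu(ct2_r, cfg),
        ctv2=ctv2_r,
        slab_range=(start, stop),
        crop_box=box,
    )
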