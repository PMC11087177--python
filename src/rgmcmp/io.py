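"""NIfTI volume I/O and YAML run configuration.

Volumes are written as NIfTI-1 with a diagonal affine built from the
voxel spacing; images as 32-bit float, masks as unsigned 8-bit. Reading
restores the array and spacing exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import LabelMask, Volume
from .network import ModelConfig
from .objective import LossConfig
from .phantom import PhantomParams
from .preprocess import PreprocessConfig
from .registration import RegistrationConfig
from .training import TrainConfig

__all__ = ["read_volume", "write_volume", "read_mask", "RunConfig"]


class VolumeIOError(ValueError):
    pass


def _affine(vol: Volume) -> np.ndarray:
    aff = np.diag([*vol.spacing, 1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    is_mask = isinstance(vol, LabelMask)
    dtype = np.uint8 if is_mask else np.float32
    img = nib.Nifti1Image(vol.array.astype(dtype), _affine(vol))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"expected a 3D volume, got {data.ndim}D payload in {path}")
    aff = img.affine
    if not np.all(np.isfinite(aff)):
        raise VolumeIOError(f"non-finite affine in {path}")
    spacing = tuple(np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(aff[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> Volume:
    data, spacing, origin = _load(path)
    return Volume(data.astype(np.float32), spacing, origin)


def read_mask(path: str | Path) -> LabelMask:
    data, spacing, origin = _load(path)
    return LabelMask((data > 0.5).astype(np.uint8), spacing, origin)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(variant="mcmp"))
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    n_cases: int = 25
    methods: list[str] = field(
        default_factory=lambda: ["rb", "dir", "scsp", "dir_mcsp", "dir_mcmp"]
    )
    seed: int = 0
    output_dir: str = "runs/run0"

    _BLOCKS = {
        "phantom": PhantomParams,
        "registration": RegistrationConfig,
        "preprocess": PreprocessConfig,
        "model": ModelConfig,
        "train": TrainConfig,
        "loss": LossConfig,
    }

    def to_dict(self) -> dict:
        d = {}
        for name in self._BLOCKS:
            block = getattr(self, name)
            d[name] = block.to_dict() if hasattr(block, "to_dict") else asdict(block)
        d.update(
            n_cases=self.n_cases,
            methods=list(self.methods),
            seed=self.seed,
            output_dir=self.output_dir,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for name, typ in cls._BLOCKS.items():
            if name not in d:
                raise ValueError(f"config is missing the required block {name!r}")
            block = d[name]
            if name == "model":
                kwargs[name] = ModelConfig.from_dict(block)
            else:
                block = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
                }
                kwargs[name] = typ(**block)
        for key in ("n_cases", "methods", "seed", "output_dir"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
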