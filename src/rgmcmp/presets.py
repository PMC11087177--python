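"""Desk-scale study presets.

The clinical-scale protocol (192×160×48 grids, base 16 filters, five
resolution levels, LR 2e-4 with plateau scheduling) is far beyond a
single CPU. These presets define the package's reduced study conditions:
a coarser phantom lattice, a 24×24×16 network grid, three-level base-4
models and a shorter, higher-LR training run sized so one full
method-comparison finishes in minutes. The method ladder, losses,
protocol structure and metrics are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import ComparisonResult, prepare_experiment, run_experiment
from .network import ModelConfig
from .objective import LossConfig
from .phantom import PhantomParams, generate_cohort
from .preprocess import PreprocessConfig
from .registration import RegistrationConfig
from .training import TrainConfig

__all__ = ["ScaledStudy", "run_ordering_study"]


@dataclass
class ScaledStudy:
    """Configuration bundle for the reduced-resolution phantom study."""

    n_cases: int = 16
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    phantom: PhantomParams = field(
        default_factory=lambda: PhantomParams(
            grid_shape=(48, 48, 24), spacing_mm=(4.0, 4.0, 5.0)
        )
    )
    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            max_iterations=150,
            pyramid_levels=4,
            grid_spacing_voxels=6,
            bspline_iterations=30,
            bspline_sampling_fraction=0.25,
            bspline_pyramid_levels=3,
        )
    )
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(
            slab_slices=16, target_shape=(32, 32, 16)
        )
    )
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(
            variant="mcmp", base_filters=8, n_levels=3
        )
    )
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(max_epochs=30, initial_lr=2e-3)
    )
    loss: LossConfig = field(default_factory=LossConfig)


def run_ordering_study(
    methods: list[str],
    seeds: list[int],
    study: ScaledStudy | None = None,
    cohort_seed: int = 1,
    verbose: bool = False,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Run the method comparison for several training seeds on one cohort.

    The cohort, registration guidance and preprocessing are deterministic
    given ``cohort_seed`` and are computed once; each entry of ``seeds``
    re-initializes and retrains the networks. Returns the per-method mean
    test metrics averaged over seeds, plus the individual results.
    """
    study = study or ScaledStudy()
    cohort = generate_cohort(study.n_cases, study.phantom, seed=cohort_seed)
    prepared = prepare_experiment(
        cohort, methods, study.registration, study.preprocess, verbose=verbose
    )
    results = []
    for s in seeds:
        cfg = TrainConfig(**{**study.train.__dict__, "seed": int(s)})
        results.append(
            run_experiment(
                cohort,
                methods,
                train_cfg=cfg,
                loss_cfg=study.loss,
                reg_cfg=study.registration,
                pre_cfg=study.preprocess,
                model_cfg=study.model,
                seed=int(s),
                fractions=study.fractions,
                prepared=prepared,
                verbose=verbose,
            )
        )
    mean_summary = (
        pd.concat([r.summary for r in results]).groupby(level=0).mean().reindex(methods)
    )
    return mean_summary, results
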