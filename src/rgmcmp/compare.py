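"""Experiment harness: run the method ladder on a cohort and tabulate
per-case DSC/HD95/ASD, paired t-tests and the delta correlation.

Methods
-------
``rb`` / ``dir``             contour propagation by rigid / B-spline
                             registration alone (no learning);
``unet3d`` / ``scsp``        direct segmentation of CT2 without guidance
                             (standard 3D U-Net reference / the
                             single-channel single-path variant);
``rb_mcsp`` / ``dir_mcsp``   registration-guided multi-channel single-path;
``rb_mcmp`` / ``dir_mcmp``   registration-guided multi-channel multi-path.

Every deep-learning method is trained once with the same TrainConfig and
scored on the identical test partition. Registration methods are scored
by propagating CTV1 directly onto the course-2 grid. The delta
correlation is the Pearson coefficient between the per-case DSC gain of
deformable over rigid registration (ΔRegistration) and the per-case DSC
gain of the DIR-guided over the RB-guided multi-path model (ΔRg-MCMP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import LabelMask
from .metrics import MetricsReport, evaluate_pair
from .network import AlignedInputs, ModelConfig, build_model
from .objective import LossConfig
from .phantom import PatientCase
from .preprocess import PreprocessConfig, preprocess_case
from .registration import RegistrationConfig, propagate, register_bspline, register_rigid
from .training import TrainConfig, train

__all__ = [
    "MethodSpec",
    "ComparisonResult",
    "METHODS",
    "run_experiment",
    "paired_ttest",
    "delta_correlation",
    "DegenerateStatisticError",
]


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined (zero variance)."""


@dataclass(frozen=True)
class MethodSpec:
    method_id: str
    guidance: str  # none | rb | dir
    variant: str | None  # network variant, or None for registration-only


METHODS: dict[str, MethodSpec] = {
    "rb": MethodSpec("rb", "rb", None),
    "dir": MethodSpec("dir", "dir", None),
    "unet3d": MethodSpec("unet3d", "none", "unet3d"),
    "scsp": MethodSpec("scsp", "none", "scsp"),
    "rb_mcsp": MethodSpec("rb_mcsp", "rb", "mcsp"),
    "dir_mcsp": MethodSpec("dir_mcsp", "dir", "mcsp"),
    "rb_mcmp": MethodSpec("rb_mcmp", "rb", "mcmp"),
    "dir_mcmp": MethodSpec("dir_mcmp", "dir", "mcmp"),
}


@dataclass
class ComparisonResult:
    per_case: pd.DataFrame  # columns: case_id, method, split, dsc, hd95_mm, asd_mm
    summary: pd.DataFrame  # per-method means over the test partition
    pvalues: dict[tuple[str, str], float]
    delta_correlation_r: float | None
    provenance: dict = field(default_factory=dict)


def paired_ttest(a, b) -> float:
    """Two-sided paired t-test p-value on the differences a − b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1D and paired (equal length)")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateStatisticError("paired differences have zero variance")
    return float(stats.ttest_rel(a, b).pvalue)


def delta_correlation(result: "ComparisonResult | pd.DataFrame") -> float:
    """Pearson R between per-case ΔRegistration and ΔRg-MCMP DSC gains."""
    df = result.per_case if isinstance(result, ComparisonResult) else result
    df = df[df["split"] == "test"] if "split" in df else df
    needed = ("rb", "dir", "rb_mcmp", "dir_mcmp")
    tables = {}
    for m in needed:
        sub = df[df["method"] == m].set_index("case_id")["dsc"]
        if len(sub) < 3:
            raise ValueError(f"need per-case DSC for {m!r} on ≥ 3 cases")
        tables[m] = sub
    cases = tables["rb"].index
    d_reg = (tables["dir"] - tables["rb"]).loc[cases].to_numpy()
    d_mcmp = (tables["dir_mcmp"] - tables["rb_mcmp"]).loc[cases].to_numpy()
    return pearson(d_reg, d_mcmp)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise DegenerateStatisticError("zero variance in a correlation input")
    return float(stats.pearsonr(x, y).statistic)


def split_cohort(cases: list[PatientCase], fractions=(0.6, 0.2, 0.2)):
    """Deterministic train/val/test split in cohort order."""
    n = len(cases)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2)
    train_c = cases[:n_train]
    val_c = cases[n_train : n_train + n_val]
    test_c = cases[n_train + n_val :]
    if not test_c:
        raise ValueError("cohort too small to split into train/val/test")
    return train_c, val_c, test_c


def _registration_guidance(case: PatientCase, mode: str, reg_cfg: RegistrationConfig):
    """Propagate course-1 image and contour onto the course-2 grid."""
    if mode == "rb":
        t = register_rigid(case.ct2, case.ct1, reg_cfg)
    elif mode == "dir":
        rigid = register_rigid(case.ct2, case.ct1, reg_cfg)
        t = register_bspline(case.ct2, case.ct1, reg_cfg, initial=rigid)
    else:
        raise ValueError(f"unknown guidance mode {mode!r}")
    act1 = propagate(case.ct1, t)
    actv1 = propagate(case.ctv1, t)
    return t, act1, actv1


def prepare_experiment(
    cohort: list[PatientCase],
    methods: list[str],
    reg_cfg: RegistrationConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    verbose: bool = False,
) -> dict:
    """Registration guidance and preprocessing for every case.

    This stage is deterministic and independent of the training seed, so a
    multi-seed study computes it once and reuses it.
    """
    reg_cfg = reg_cfg or RegistrationConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    guidance_modes = sorted(
        {METHODS[m].guidance for m in methods if m in METHODS and METHODS[m].guidance != "none"}
    )
    guidance: dict[tuple[str, str], tuple] = {}
    for mode in guidance_modes:
        for case in cohort:
            if verbose:
                print(f"[register:{mode}] {case.case_id}")
            guidance[(case.case_id, mode)] = _registration_guidance(case, mode, reg_cfg)

    # preprocessing per (case, guidance-mode); unguided methods reuse the
    # course-2 channels of the first available guided pipeline, or an
    # identity-guidance pipeline when no registration method was requested
    pre: dict[tuple[str, str], object] = {}
    modes_for_pre = guidance_modes or ["identity"]
    for mode in modes_for_pre:
        for case in cohort:
            if mode == "identity":
                act1, actv1 = case.ct1, case.ctv1
            else:
                _, act1, actv1 = guidance[(case.case_id, mode)]
            pre[(case.case_id, mode)] = preprocess_case(
                act1, actv1, case.ct2, case.ctv2, pre_cfg
            )
    return {"guidance": guidance, "pre": pre, "modes_for_pre": modes_for_pre}


def run_experiment(
    cohort: list[PatientCase],
    methods: list[str],
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    reg_cfg: RegistrationConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    fractions=(0.6, 0.2, 0.2),
    prepared: dict | None = None,
    verbose: bool = False,
) -> ComparisonResult:
    """Run every requested method on a shared split of the cohort.

    ``model_cfg`` provides the architecture scale (base filters, levels);
    its variant/in_channels fields are overridden per method. The same
    TrainConfig drives every deep-learning method. Every method — including
    the registration-only ones — is scored on the preprocessed grid, so
    comparisons are not confounded by grid resolution.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    reg_cfg = reg_cfg or RegistrationConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    base_model = model_cfg or ModelConfig()

    seen, ordered = set(), []
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
        if m in seen:
            warnings.warn(f"duplicate method {m!r} ignored", stacklevel=2)
            continue
        seen.add(m)
        ordered.append(m)

    train_c, val_c, test_c = split_cohort(cohort, fractions)
    split_of = {c.case_id: s for cs, s in ((train_c, "train"), (val_c, "val"), (test_c, "test")) for c in cs}

    if prepared is None:
        prepared = prepare_experiment(cohort, ordered, reg_cfg, pre_cfg, verbose=verbose)
    guidance, pre = prepared["guidance"], prepared["pre"]
    modes_for_pre = prepared["modes_for_pre"]

    rows: list[MetricsReport] = []

    def _score(mask_pred: LabelMask, gt: LabelMask, case_id: str, method: str):
        rep = evaluate_pair(mask_pred, gt, case_id=case_id, method_id=method)
        rows.append(rep)

    for m in ordered:
        spec = METHODS[m]
        if spec.variant is None:  # registration-only, scored in network space
            for case in test_c:
                pc = pre[(case.case_id, spec.guidance)]
                _score(pc.actv1, pc.ctv2, case.case_id, m)
            continue

        mode = spec.guidance if spec.guidance != "none" else modes_for_pre[0]
        multi = spec.variant in ("mcsp", "mcmp")

        def _xy(case):
            pc = pre[(case.case_id, mode)]
            if multi:
                x = AlignedInputs(pc.act1.array, pc.actv1.array, pc.ct2.array).stacked()
            else:
                x = pc.ct2.array[None].astype(np.float32)
            return x, pc.ctv2.array

        cfg_m = ModelConfig(
            variant=spec.variant,
            in_channels=3 if multi else 1,
            n_classes=base_model.n_classes,
            base_filters=base_model.base_filters,
            n_levels=base_model.n_levels,
            lrelu_alpha=base_model.lrelu_alpha,
            use_channel_attention=base_model.use_channel_attention,
            ca_reduction=base_model.ca_reduction,
            deep_supervision_heads=base_model.deep_supervision_heads,
        )
        net = build_model(cfg_m, seed=seed)
        if verbose:
            print(f"[train:{m}] {net.parameter_count()} params")
        net, hist = train(
            net,
            [_xy(c) for c in train_c],
            [_xy(c) for c in val_c],
            loss_cfg,
            train_cfg,
            verbose=verbose,
        )
        for case in test_c:
            x, _ = _xy(case)
            pc = pre[(case.case_id, mode)]
            pred = LabelMask(net.predict_mask(x), pc.ctv2.spacing)
            _score(pred, pc.ctv2, case.case_id, m)

    per_case = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "method": r.method_id,
                "split": split_of.get(r.case_id, "test"),
                "dsc": r.dsc,
                "hd95_mm": r.hd95_mm,
                "asd_mm": r.asd_mm,
            }
            for r in rows
        ]
    )
    summary = (
        per_case[per_case["split"] == "test"]
        .groupby("method")[["dsc", "hd95_mm", "asd_mm"]]
        .mean()
        .reindex(ordered)
    )

    pvalues: dict[tuple[str, str], float] = {}
    test_tbl = per_case[per_case["split"] == "test"].pivot(
        index="case_id", columns="method", values="dsc"
    )
    if len(test_tbl) >= 3:
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                try:
                    pvalues[(a, b)] = paired_ttest(test_tbl[a], test_tbl[b])
                except DegenerateStatisticError:
                    pvalues[(a, b)] = float("nan")

    try:
        r = delta_correlation(per_case)
    except (ValueError, DegenerateStatisticError):
        r = None

    return ComparisonResult(
        per_case=per_case,
        summary=summary,
        pvalues=pvalues,
        delta_correlation_r=r,
        provenance={
            "seed": seed,
            "n_cases": len(cohort),
            "split": {s: [c.case_id for c in cs] for cs, s in ((train_c, "train"), (val_c, "val"), (test_c, "test"))},
            "methods": ordered,
            "train_cfg": train_cfg.__dict__.copy(),
            "reg_cfg": reg_cfg.__dict__.copy(),
            "multiple_testing_correction": "none",
        },
    )
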