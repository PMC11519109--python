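"""End-to-end experiment runner: phantom -> undersample -> reconstruct ->
detect -> evaluate -> report.

For every (acceleration, reconstruction method) condition the runner
produces per-case visual metrics (SSIM/PSNR against the fully sampled
reference), a cohort FROC with pAUC and bootstrap CI on the held-out test
patients, the paired statistical comparisons (Wilcoxon on SSIM,
permutation tests on pAUC, patient-level ROC at the reference-derived
threshold), the split manifest, and a provenance record (config hash,
seeds, package version) sufficient to rerun bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .froc import (
    CandidateParams,
    FrocResult,
    PatientDetections,
    bootstrap_pauc_ci,
    extract_candidates,
    froc_curve,
)
from .kspace import MaskConfig, make_undersampling_mask, undersample_volume
from .models import (
    DetectTrainConfig,
    ReconTrainConfig,
    SurrogateParams,
    predict_heatmap,
    reconstruct,
    surrogate_detect,
    train_detector,
    train_reconstructor,
)
from .phantom import PhantomCase, PhantomConfig, generate_cohort
from .preprocess import (
    detect_chain,
    detect_chain_labelmap,
    minmax_normalize,
    recon_chain,
    recon_chain_labelmap,
)
from .splits import make_split_manifest
from .stats import (
    patient_roc,
    patient_score,
    permutation_test_pauc,
    youden_threshold,
)
from .visual_metrics import compare_ssim_paired, imagqm
from .volume import ImageVolume

log = logging.getLogger("diagqm.experiment")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """One self-contained experiment specification.

    ``accelerations`` must contain 1 (the fully sampled reference
    condition).  Desk-scale defaults keep the pipeline CPU-friendly; the
    nested module configs carry the reference protocol hyperparameters.
    ``crop_size=None`` means "the phantom grid", making the preprocessing
    chains near-identity.
    """

    n_cases: int = 40
    accelerations: tuple[int, ...] = (1, 4, 8)
    recon_methods: tuple[str, ...] = ("naive", "learned")
    detector: str = "surrogate"  # or "trained"
    phantom: PhantomConfig = field(
        default_factory=lambda: PhantomConfig(
            volume_shape=(96, 96, 12), voxel_spacing=(1.0, 1.0, 3.0)
        )
    )
    mask: MaskConfig = field(default_factory=MaskConfig)
    recon_train: ReconTrainConfig = field(
        default_factory=lambda: ReconTrainConfig(
            model_scale=6, epochs=12, learning_rate=2e-3
        )
    )
    detect_train: DetectTrainConfig = field(
        default_factory=lambda: DetectTrainConfig(model_scale=6, epochs=6)
    )
    candidates: CandidateParams = field(default_factory=CandidateParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    crop_size: tuple[int, int, int] | None = None
    n_bootstrap: int = 200
    n_permutations: int = 500
    train_fraction: float = 0.8
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if 1 not in self.accelerations:
            raise ValueError("accelerations must include 1 (the reference condition)")
        if any(r < 1 for r in self.accelerations):
            raise ValueError("accelerations must be >= 1")
        bad = set(self.recon_methods) - {"naive", "learned"}
        if bad:
            raise ValueError(f"unknown reconstruction methods: {sorted(bad)}")
        if self.detector not in ("surrogate", "trained"):
            raise ValueError("detector must be 'surrogate' or 'trained'")
        if self.n_cases < 4:
            raise ValueError("need at least 4 cases")

    # -- config file round-trip ------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        def build(typ, val):
            if val is None or not dataclasses.is_dataclass(typ):
                return val
            fields = {f.name: f for f in dataclasses.fields(typ)}
            kwargs = {}
            for k, v in val.items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {typ.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return typ(**kwargs)

        d = dict(d)
        for key, typ in (
            ("phantom", PhantomConfig),
            ("mask", MaskConfig),
            ("recon_train", ReconTrainConfig),
            ("detect_train", DetectTrainConfig),
            ("candidates", CandidateParams),
            ("surrogate", SurrogateParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = build(typ, sub)
        for key in ("accelerations", "recon_methods", "crop_size"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Everything the runner computed, ready for serialisation."""

    conditions: list[str]
    imagqm_table: pd.DataFrame
    froc: dict[str, FrocResult]
    ssim_comparisons: dict[str, dict[str, float]]
    permutation_tests: dict[str, dict[str, float]]
    patient_roc: dict[str, dict[str, float]]
    manifest: pd.DataFrame
    provenance: dict[str, Any]

    def summary(self) -> dict[str, Any]:
        return {
            "conditions": self.conditions,
            "ssim": {
                c: float(
                    self.imagqm_table.loc[self.imagqm_table.condition == c, "ssim"].mean()
                )
                for c in self.conditions
                if not self.imagqm_table.empty
                and c in set(self.imagqm_table.condition)
            },
            "pauc": {c: r.pauc for c, r in self.froc.items()},
            "pauc_ci": {c: r.ci for c, r in self.froc.items()},
            "ssim_comparisons": self.ssim_comparisons,
            "permutation_tests": self.permutation_tests,
            "patient_roc": self.patient_roc,
            "provenance": self.provenance,
        }


def _condition_name(method: str, acceleration: int) -> str:
    return "R1" if acceleration == 1 else f"R{acceleration}_{method}"


def _condition_volumes(
    cohort: list[PhantomCase],
    config: ExperimentConfig,
    crop: tuple[int, int, int],
    train_ids: set[str],
) -> dict[str, dict[str, ImageVolume]]:
    """Reference and per-condition volumes on the reconstruction-chain grid."""
    in_plane = config.phantom.voxel_spacing[0]
    volumes: dict[str, dict[str, ImageVolume]] = {"R1": {}}
    for case in cohort:
        volumes["R1"][case.patient_id] = recon_chain(
            case.image, crop_size=crop, in_plane_spacing=in_plane
        )
    accels = [r for r in config.accelerations if r > 1]
    for r in accels:
        name = f"R{r}_naive"
        volumes[name] = {}
        for idx, case in enumerate(cohort):
            n_lines = case.image.shape[config.mask.axis]
            mask = make_undersampling_mask(
                n_lines,
                dataclasses.replace(
                    config.mask, acceleration=float(r), seed=config.seed * 100003 + idx
                ),
            )
            aliased = undersample_volume(case.image, mask)
            volumes[name][case.patient_id] = recon_chain(
                aliased, crop_size=crop, in_plane_spacing=in_plane
            )
    if "learned" in config.recon_methods:
        for r in accels:
            t0 = time.perf_counter()
            pairs = [
                (volumes[f"R{r}_naive"][c.patient_id], volumes["R1"][c.patient_id])
                for c in cohort
                if c.patient_id in train_ids
            ]
            model = train_reconstructor(pairs, config.recon_train)
            name = f"R{r}_learned"
            volumes[name] = {
                pid: reconstruct(model, vol)
                for pid, vol in volumes[f"R{r}_naive"].items()
            }
            log.info(
                "trained R%d reconstructor on %d pairs in %.1fs (val loss %.4f)",
                r,
                len(pairs),
                time.perf_counter() - t0,
                model.val_losses[-1] if model.val_losses else float("nan"),
            )
    return volumes


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentReport:
    """Execute the full pipeline for every (acceleration, method) condition."""
    t_start = time.perf_counter()
    cohort = generate_cohort(config.phantom, config.n_cases)
    ids = [c.patient_id for c in cohort]
    sites = [c.site for c in cohort]
    manifest = make_split_manifest(
        ids, sites, config.train_fraction, config.n_folds, config.seed
    )
    train_ids = set(manifest.loc[manifest.role == "train", "patient_id"])
    test_ids = [i for i in ids if i not in train_ids]
    if not any(c.patient_label for c in cohort if c.patient_id in set(test_ids)):
        raise ValueError(
            "the held-out test split contains no lesion-bearing patient; "
            "increase n_cases or the lesion prevalence"
        )
    crop = config.crop_size or config.phantom.volume_shape
    in_plane = config.phantom.voxel_spacing[0]

    volumes = _condition_volumes(cohort, config, crop, train_ids)
    conditions = ["R1"] + [
        _condition_name(m, r)
        for r in config.accelerations
        if r > 1
        for m in config.recon_methods
    ]

    # ground truth on the reconstruction-chain grid (surrogate detector) or
    # the detection-chain grid (trained detector)
    lesions_by_id = {}
    case_by_id = {c.patient_id: c for c in cohort}

    # ---- detection stage -------------------------------------------------
    detections: dict[str, dict[str, PatientDetections]] = {}
    if config.detector == "surrogate":
        for pid in ids:
            lesions_by_id[pid] = recon_chain_labelmap(
                case_by_id[pid].lesions, crop_size=crop, in_plane_spacing=in_plane
            )
        for cond in conditions:
            detections[cond] = {}
            for pid in test_ids:
                heat = surrogate_detect(volumes[cond][pid], config.surrogate)
                cands = extract_candidates(heat, config.candidates)
                detections[cond][pid] = PatientDetections(
                    candidates=tuple(cands), lesions=lesions_by_id[pid]
                )
    else:
        spacing = config.phantom.voxel_spacing
        for pid in ids:
            lesions_by_id[pid] = detect_chain_labelmap(
                case_by_id[pid].lesions, crop_size=crop, target_spacing=spacing
            )
        t0 = time.perf_counter()
        det_cfg = dataclasses.replace(
            config.detect_train,
            n_folds=config.n_folds,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        train_cohort = [
            (
                detect_chain(volumes["R1"][pid], crop_size=crop, target_spacing=spacing),
                lesions_by_id[pid],
            )
            for pid in ids
        ]
        ensemble = train_detector(train_cohort, det_cfg, patient_ids=ids, sites=sites)
        log.info("trained detector ensemble in %.1fs", time.perf_counter() - t0)
        for cond in conditions:
            detections[cond] = {}
            for pid in test_ids:
                det_in = detect_chain(
                    volumes[cond][pid], crop_size=crop, target_spacing=spacing
                )
                heat = predict_heatmap(ensemble, det_in, provenance=cond)
                cands = extract_candidates(heat, config.candidates)
                detections[cond][pid] = PatientDetections(
                    candidates=tuple(cands), lesions=lesions_by_id[pid]
                )

    # ---- visual metrics --------------------------------------------------
    rows = []
    for cond in conditions:
        if cond == "R1":
            continue
        for pid in test_ids:
            ref = volumes["R1"][pid]
            res = imagqm(ref, volumes[cond][pid])
            rows.append(
                {"patient_id": pid, "condition": cond, "ssim": res.ssim, "psnr": res.psnr}
            )
    imagqm_table = pd.DataFrame(rows)

    ssim_comparisons: dict[str, dict[str, float]] = {}
    for r in config.accelerations:
        if r == 1 or {"naive", "learned"} - set(config.recon_methods):
            continue
        a = imagqm_table[imagqm_table.condition == f"R{r}_learned"].sort_values("patient_id")
        b = imagqm_table[imagqm_table.condition == f"R{r}_naive"].sort_values("patient_id")
        cmp_res = compare_ssim_paired(a.ssim.to_numpy(), b.ssim.to_numpy())
        ssim_comparisons[f"R{r}_learned_vs_naive"] = {
            "mean_learned": cmp_res.mean_a,
            "sd_learned": cmp_res.sd_a,
            "mean_naive": cmp_res.mean_b,
            "sd_naive": cmp_res.sd_b,
            "wilcoxon_p": cmp_res.p_value,
        }

    # ---- FROC / pAUC -----------------------------------------------------
    froc_results: dict[str, FrocResult] = {}
    for cond in conditions:
        cohort_dets = [detections[cond][pid] for pid in test_ids]
        res = froc_curve(cohort_dets)
        ci = None
        if config.n_bootstrap > 0 and len(test_ids) >= 10:
            lo, hi, n_redrawn = bootstrap_pauc_ci(
                cohort_dets, n_boot=config.n_bootstrap, seed=config.seed
            )
            if n_redrawn:
                log.warning("%s: %d degenerate bootstrap resamples redrawn", cond, n_redrawn)
            ci = (lo, hi)
        froc_results[cond] = dataclasses.replace(res, ci=ci)

    permutation_tests: dict[str, dict[str, float]] = {}
    ref_dets = [detections["R1"][pid] for pid in test_ids]
    for cond in conditions:
        if cond == "R1":
            continue
        perm = permutation_test_pauc(
            ref_dets,
            [detections[cond][pid] for pid in test_ids],
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        permutation_tests[f"R1_vs_{cond}"] = {
            "observed_diff": perm.observed_diff,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "exact": float(perm.exact),
        }

    # ---- patient-level ROC at the reference operating point --------------
    labels = [case_by_id[pid].patient_label for pid in test_ids]
    roc_out: dict[str, dict[str, float]] = {}
    thr: float | None = None
    if len(set(labels)) == 2:
        ref_scores = [patient_score(detections["R1"][pid]) for pid in test_ids]
        thr = youden_threshold(ref_scores, labels)
        for cond in conditions:
            scores = [patient_score(detections[cond][pid]) for pid in test_ids]
            r = patient_roc(scores, labels, threshold=thr)
            roc_out[cond] = {
                "auc": r.auc,
                "threshold": r.threshold,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "ppv": r.ppv,
                "npv": r.npv,
            }
    else:
        log.warning("test split is single-class; patient ROC skipped")

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_cases": config.n_cases,
        "n_test": len(test_ids),
        "runtime_s": round(time.perf_counter() - t_start, 1),
    }
    report = ExperimentReport(
        conditions=conditions,
        imagqm_table=imagqm_table,
        froc=froc_results,
        ssim_comparisons=ssim_comparisons,
        permutation_tests=permutation_tests,
        patient_roc=roc_out,
        manifest=manifest,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_report(report, config, Path(out_dir))
    return report


def _write_report(
    report: ExperimentReport, config: ExperimentConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report.manifest.to_csv(out / "split_manifest.csv", index=False)
    report.imagqm_table.to_csv(out / "imagqm_per_case.csv", index=False)
    for cond, res in report.froc.items():
        pd.DataFrame(
            {
                "threshold": res.thresholds,
                "sensitivity": res.sensitivities,
                "fp_per_patient": res.fp_per_patient,
            }
        ).to_csv(out / f"froc_points_{cond}.csv", index=False)
    (out / "results.json").write_text(json.dumps(report.summary(), indent=2, default=str))
    try:
        _plot_report(report, out)
    except Exception as exc:  # plots are best-effort side outputs
        log.warning("plot export failed: %s", exc)


def _plot_report(report: ExperimentReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.imagqm_table.empty:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        conds = sorted(report.imagqm_table.condition.unique())
        for ax, metric in zip(axes, ("ssim", "psnr")):
            data = [
                report.imagqm_table.loc[
                    report.imagqm_table.condition == c, metric
                ].to_numpy()
                for c in conds
            ]
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(conds) + 1), conds, rotation=30)
            ax.set_ylabel(metric.upper())
        fig.tight_layout()
        fig.savefig(out / "imagqm_violin.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for cond, res in report.froc.items():
        label = f"{cond} (pAUC {res.pauc:.2f})"
        ax.plot(res.fp_per_patient, res.sensitivities, marker=".", label=label)
    ax.set_xscale("log")  # display convention; pAUC integrates on the linear axis
    ax.set_xlabel("false positives per patient")
    ax.set_ylabel("lesion sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "froc_curves.png", dpi=120)
    plt.close(fig)
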