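"""End-to-end experiment orchestration.

Reproduces the three-arm comparison on phantom datasets: a detector trained
with (A) original FLAIR + T1, (B) FLAIR only, or (C) FLAIR + synthetic T1
(T1S) generated from the FLAIR itself. All arms share the preprocessing,
the train/test split (disjoint at the case level), the detector
configuration and the seeds, so the paired per-case comparison across arms
isolates the effect of the detector's input channels.

For the synthetic arm the synthesizer is trained on the training cases and
then applied to every case of both sets — training cases included — so the
detector never sees an original T1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import detection, metrics, phantom, preprocess, synthesis
from .clustering import cluster_intensities
from .volumes import LongitudinalCase

ARMS = ("baseline", "flair_only", "synthetic")
ARM_MODALITIES = {
    "baseline": ("FLAIR", "T1"),
    "flair_only": ("FLAIR",),
    "synthetic": ("FLAIR", "T1S"),
}


@dataclasses.dataclass
class ExperimentConfig:
    """One experimental arm over one phantom manifest."""

    arm: str
    manifest: str
    out_dir: str = "results"
    c: int = 7
    threshold: float = 0.5
    min_voxels: int = 3
    n_test: int = 4
    seed: int = 0
    train_synthesizer: bool = True
    synth_model_path: Optional[str] = None
    synth_steps: int = 80
    synth_base_width: int = 4
    synth_adv_weight: float = 1.0
    detect_steps: int = 300
    detect_base_width: int = 8
    detect_batch_size: int = 1
    detect_learning_rate: float = 2e-3
    smoothness_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.arm == "synthetic" and not (
            self.train_synthesizer or self.synth_model_path
        ):
            raise ValueError(
                "arm=synthetic requires a synthesis model path or "
                "train_synthesizer=true"
            )


def load_config(path) -> ExperimentConfig:
    """Read a flat YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = sorted(set(raw) - fields)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    missing = {"arm", "manifest"} - set(raw)
    if missing:
        raise ValueError(f"missing required config key(s): {', '.join(sorted(missing))}")
    return ExperimentConfig(**raw)


def split_cases(case_ids: Sequence[str], n_test: int, seed: int) -> Tuple[List[str], List[str]]:
    """Deterministic case-level train/test split (never patch-level)."""
    ids = sorted(case_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    test = sorted(ids[:n_test])
    train = sorted(ids[n_test:])
    if set(train) & set(test):
        raise ValueError("split leakage: case present in both train and test")
    if not train or not test:
        raise ValueError("both train and test splits must be non-empty")
    return train, test


def preprocess_case(case: LongitudinalCase, dof: str = "rigid") -> LongitudinalCase:
    """Register baseline onto the follow-up grid (one transform estimated on
    FLAIR, applied to every baseline modality) and normalize all volumes to
    [0, 1] within the brain mask."""
    ref = case.followup["FLAIR"]
    t = preprocess.affine_register(case.baseline["FLAIR"], ref, dof=dof)
    baseline = {}
    for mod, vol in case.baseline.items():
        moved = preprocess.resample(vol, t, ref, "linear")
        baseline[mod] = preprocess.normalize01(moved)
    followup = {mod: preprocess.normalize01(vol) for mod, vol in case.followup.items()}
    return LongitudinalCase(case.case_id, baseline, followup, case.new_lesion_mask)


def _attach_t1s(
    cases: Dict[str, LongitudinalCase],
    model: synthesis.SynthesisModel,
    c: int,
    seed: int,
) -> Dict[str, float]:
    """Cluster each FLAIR and synthesize T1S for both timepoints of every
    case; returns per-case SSIM and MAE of follow-up T1S vs real T1 when
    available."""
    ssims, maes = {}, {}
    for cid, case in cases.items():
        for tp_name, tp in (("baseline", case.baseline), ("followup", case.followup)):
            cm = cluster_intensities(tp["FLAIR"], c, smoothing=0, seed=seed)
            t1s = synthesis.synthesize_t1(model, tp["FLAIR"], cm)
            tp["T1S"] = t1s
            if tp_name == "followup" and "T1" in tp:
                ssims[cid] = metrics.ssim(tp["T1"], t1s)
                maes[cid] = metrics.mae(tp["T1"], t1s)
    return ssims, maes


@dataclasses.dataclass
class ArmReport:
    arm: str
    scores: pd.DataFrame  # per-case rows
    model_path: str
    run_record: Dict[str, object]
    synth_ssim: Dict[str, float] = dataclasses.field(default_factory=dict)
    synth_mae: Dict[str, float] = dataclasses.field(default_factory=dict)


def run_experiment(
    cfg: ExperimentConfig,
    preprocessed: Optional[Dict[str, LongitudinalCase]] = None,
) -> ArmReport:
    """Run one arm: (optionally synthesize T1S), train the detector on the
    training split, evaluate lesion-wise scores on the held-out split.

    ``preprocessed`` lets callers (run_all_arms, tests) share the loaded and
    preprocessed cases across arms.
    """
    t_start = time.time()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(cfg.manifest)
    manifest = pd.read_csv(manifest_path, sep="\t")

    if preprocessed is None:
        preprocessed = {}
        for _, row in manifest.iterrows():
            case = phantom.load_case(manifest_path.parent / row["path"], row["case_id"])
            preprocessed[row["case_id"]] = preprocess_case(case)
    cases = preprocessed

    train_ids, test_ids = split_cases(list(cases), cfg.n_test, cfg.seed)

    synth_ssim: Dict[str, float] = {}
    synth_mae: Dict[str, float] = {}
    synth_path = ""
    if cfg.arm == "synthetic":
        if cfg.synth_model_path:
            smodel = synthesis.SynthesisModel.load(cfg.synth_model_path)
            synth_path = cfg.synth_model_path
        else:
            gcfg = synthesis.GeneratorConfig(
                in_channels=cfg.c, base_width=cfg.synth_base_width
            )
            tcfg = synthesis.SynthTrainConfig(
                n_steps=cfg.synth_steps,
                adv_weight=cfg.synth_adv_weight,
                seed=cfg.seed,
            )
            smodel = synthesis.train_synthesizer(
                [cases[cid] for cid in train_ids], cfg.c, gcfg, None, tcfg, seed=cfg.seed
            )
            synth_path = str(out_dir / f"synth_{cfg.arm}.npz")
            smodel.save(synth_path)
        # synthetic T1 for *all* cases, training set included
        synth_ssim, synth_mae = _attach_t1s(cases, smodel, cfg.c, cfg.seed)

    mods = ARM_MODALITIES[cfg.arm]
    dcfg = detection.DetectionConfig(
        modalities=mods,
        base_width=cfg.detect_base_width,
        n_steps=cfg.detect_steps,
        batch_size=cfg.detect_batch_size,
        learning_rate=cfg.detect_learning_rate,
        smoothness_weight=cfg.smoothness_weight,
        seed=cfg.seed,
    )
    dmodel = detection.train_detector([cases[cid] for cid in train_ids], dcfg, seed=cfg.seed)
    model_path = str(out_dir / f"detector_{cfg.arm}.npz")
    dmodel.save(model_path)

    rows = []
    for cid in test_ids:
        case = cases[cid]
        prob = detection.predict_new_lesions(dmodel, case)
        pred = detection.postprocess(prob, cfg.threshold, cfg.min_voxels)
        gt_lab = metrics.label_components(
            case.new_lesion_mask.data if case.new_lesion_mask is not None else np.zeros(prob.shape)
        )
        s = metrics.detection_scores(*metrics.match_lesions(pred.data, gt_lab))
        rows.append(
            {
                "case_id": cid,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "sensitivity": s.sensitivity,
                "fdr": s.fdr,
                "precision": s.precision,
            }
        )
    scores = pd.DataFrame(rows)
    scores_path = out_dir / f"scores_{cfg.arm}.tsv"
    scores.to_csv(scores_path, sep="\t", index=False, float_format="%.6f")

    record = {
        "arm": cfg.arm,
        "config": dataclasses.asdict(cfg),
        "train_ids": train_ids,
        "test_ids": test_ids,
        "detector_modalities": list(mods),
        "manifest_sha256": hashlib.sha256(manifest_path.read_bytes()).hexdigest(),
        "scores_sha256": hashlib.sha256(scores_path.read_bytes()).hexdigest(),
        "synth_model": synth_path,
        "wall_time_s": round(time.time() - t_start, 1),
    }
    with open(out_dir / f"run_record_{cfg.arm}.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return ArmReport(
        arm=cfg.arm,
        scores=scores,
        model_path=model_path,
        run_record=record,
        synth_ssim=synth_ssim,
        synth_mae=synth_mae,
    )


def compare_arms(reports: Sequence[ArmReport], metric: str = "sensitivity") -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank table across arms on a
    per-case metric (undefined cases dropped pairwise)."""
    rows = []
    for i, ra in enumerate(reports):
        for rb in reports[i + 1 :]:
            merged = ra.scores.merge(rb.scores, on="case_id", suffixes=("_a", "_b"))
            try:
                p = metrics.compare_models(
                    merged[f"{metric}_a"].to_numpy(), merged[f"{metric}_b"].to_numpy()
                )
            except ValueError:
                # fewer than 6 defined pairs: the signed-rank test is not
                # applicable; report the pairing with an undefined p-value
                p = float("nan")
            rows.append(
                {
                    "arm_a": ra.arm,
                    "arm_b": rb.arm,
                    "metric": metric,
                    "n_pairs": len(merged),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def run_all_arms(
    base_cfg: ExperimentConfig, arms: Sequence[str] = ARMS
) -> Tuple[Dict[str, ArmReport], pd.DataFrame]:
    """Run several arms on the same preprocessed cases, split and seed, then
    emit the pairwise Wilcoxon comparison table."""
    manifest_path = Path(base_cfg.manifest)
    manifest = pd.read_csv(manifest_path, sep="\t")
    cases = {}
    for _, row in manifest.iterrows():
        case = phantom.load_case(manifest_path.parent / row["path"], row["case_id"])
        cases[row["case_id"]] = preprocess_case(case)

    reports = {}
    for arm in arms:
        cfg = dataclasses.replace(base_cfg, arm=arm)
        reports[arm] = run_experiment(cfg, preprocessed=cases)
    table = compare_arms(list(reports.values()))
    table.to_csv(Path(base_cfg.out_dir) / "wilcoxon_comparison.tsv", sep="\t", index=False)
    return reports, table
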