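"""Longitudinal new-lesion detection: joint deformable registration and
segmentation, trained end-to-end.

Per input modality, a 3D U-Net predicts a dense displacement field that
nonlinearly registers the baseline patch onto the follow-up patch; its
unsupervised loss is a masked mean-squared appearance difference plus a
smoothness penalty on the local spatial variation of the field. The warped
baselines and follow-ups of all modalities are concatenated into a second
3D U-Net that produces a two-class voxel probability map of new lesions,
trained with voxelwise cross-entropy. Both sub-networks share one
computation graph, so segmentation gradients flow back through the warp
into the registration networks.

Inference tiles 32^3 patches at stride 16 with Hann blending, then applies
the detection rules: voxels with probability >= 0.5 (inclusive) belong to a
lesion, and a lesion must comprise at least three 26-connected voxels.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import nn
from .synthesis import blend_patches, patch_origins
from .volumes import LongitudinalCase, Volume


@dataclasses.dataclass
class DeformationField:
    """Per-voxel displacement vectors (3, D, H, W), voxel units."""

    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float32)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must be (3, D, H, W)")


def warp(vol: Volume, field: DeformationField) -> Volume:
    """Resample ``vol`` at v + displacement(v), trilinear, 0 outside."""
    if field.displacement.shape[1:] != vol.shape:
        raise ValueError("field grid does not match the volume grid")
    out, _ = nn.warp3d(
        vol.data.astype(np.float32)[None, None],
        field.displacement[None].astype(np.float32),
    )
    return Volume(out[0, 0], vol.affine.copy(), vol.mask)


def registration_loss(
    warped: Volume,
    fixed: Volume,
    field: DeformationField,
    smoothness_weight: float = 1.0,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Masked MSE appearance term + lambda x squared-forward-difference
    smoothness of the displacement field."""
    if warped.shape != fixed.shape:
        raise ValueError("grids do not match")
    if mask is None:
        mask = fixed.get_mask()
    if not mask.any():
        raise ValueError("empty mask")
    diff = warped.data[mask].astype(np.float64) - fixed.data[mask].astype(np.float64)
    appearance = float(np.mean(diff**2))
    smooth, _ = nn.smoothness_penalty(field.displacement[None].astype(np.float64))
    return appearance + smoothness_weight * smooth


@dataclasses.dataclass
class DetectionConfig:
    """FLAIR is always an input; ``modalities`` may add T1 or T1S. Channel
    count into the segmentation net is 2 per modality (warped baseline +
    follow-up)."""

    modalities: Tuple[str, ...] = ("FLAIR",)
    patch_size: int = 32
    patch_stride: int = 16
    smoothness_weight: float = 1.0
    learning_rate: float = 2e-3
    n_steps: int = 300
    batch_size: int = 1
    base_width: int = 8
    depth: int = 2
    lesion_class_weight: float = 35.0  # 0 = auto (inverse frequency, capped)
    min_brain_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        if len(self.modalities) == 0:
            raise ValueError("empty modality set")
        if "FLAIR" not in self.modalities:
            raise ValueError("FLAIR must always be included")


@dataclasses.dataclass
class DetectionModel:
    """One registration U-Net per modality + one segmentation U-Net."""

    reg_nets: Dict[str, nn.UNet3D]
    seg_net: nn.UNet3D
    cfg: DetectionConfig
    history: Dict[str, List[float]]
    provenance: Dict[str, object] = dataclasses.field(default_factory=dict)

    def save(self, path) -> None:
        header = {
            "format": "t1synth-detection-v1",
            "cfg": dataclasses.asdict(self.cfg),
            "history": self.history,
            "provenance": self.provenance,
        }
        arrays = {}
        for mod in self.cfg.modalities:
            for i, a in enumerate(self.reg_nets[mod].state()):
                arrays[f"reg_{mod}_{i}"] = a
        for i, a in enumerate(self.seg_net.state()):
            arrays[f"seg_{i}"] = a
        buf = io.BytesIO()
        np.savez(buf, header=json.dumps(header), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path) -> "DetectionModel":
        with np.load(Path(path), allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format") != "t1synth-detection-v1":
                raise ValueError("not a t1synth detection model file")
            cfg_d = header["cfg"]
            cfg_d["modalities"] = tuple(cfg_d["modalities"])
            cfg = DetectionConfig(**cfg_d)
            model = build_detection_model(cfg)
            for mod in cfg.modalities:
                net = model.reg_nets[mod]
                net.load_state(
                    [z[f"reg_{mod}_{i}"] for i in range(len(net.state()))]
                )
            model.seg_net.load_state(
                [z[f"seg_{i}"] for i in range(len(model.seg_net.state()))]
            )
        model.history = {k: list(v) for k, v in header["history"].items()}
        model.provenance = header.get("provenance", {})
        return model


def build_detection_model(cfg: DetectionConfig) -> DetectionModel:
    """Untrained model; the registration heads are zero-initialized so
    training starts from the identity warp."""
    rng = np.random.default_rng(cfg.seed)
    reg_nets = {
        mod: nn.UNet3D(
            cin=2,
            cout=3,
            base_width=cfg.base_width,
            depth=cfg.depth,
            rng=rng,
            head_zero_init=True,
        )
        for mod in cfg.modalities
    }
    seg_net = nn.UNet3D(
        cin=2 * len(cfg.modalities),
        cout=2,
        base_width=cfg.base_width,
        depth=cfg.depth,
        rng=rng,
    )
    return DetectionModel(
        reg_nets=reg_nets, seg_net=seg_net, cfg=cfg, history={"total": [], "ce": [], "reg": []}
    )


def _case_patches(
    case: LongitudinalCase, cfg: DetectionConfig
) -> List[Tuple[Tuple[int, int, int], Dict[str, np.ndarray], Dict[str, np.ndarray], np.ndarray, np.ndarray]]:
    """(origin, baseline patches, follow-up patches, gt patch, mask patch)."""
    for mod in cfg.modalities:
        if mod not in case.baseline or mod not in case.followup:
            raise ValueError(f"case {case.case_id}: missing modality {mod}")
    ref = case.followup["FLAIR"]
    dims = ref.shape
    mask = ref.get_mask()
    gt = (
        case.new_lesion_mask.data > 0
        if case.new_lesion_mask is not None
        else np.zeros(dims, dtype=bool)
    )
    s = cfg.patch_size
    out = []
    for oz, oy, ox in patch_origins(dims, s, cfg.patch_stride):
        sl = (slice(oz, oz + s), slice(oy, oy + s), slice(ox, ox + s))
        if mask[sl].mean() < cfg.min_brain_fraction:
            continue
        base = {m: case.baseline[m].data[sl].astype(np.float32) for m in cfg.modalities}
        fu = {m: case.followup[m].data[sl].astype(np.float32) for m in cfg.modalities}
        out.append(((oz, oy, ox), base, fu, gt[sl], mask[sl]))
    return out


def _forward_batch(model: DetectionModel, base, fu, train: bool):
    """Run registration + warp + segmentation on stacked batches.

    base/fu: {modality: (N, s, s, s)}. Returns (logits, caches).
    """
    cfg = model.cfg
    seg_in = []
    caches = {}
    for mod in cfg.modalities:
        b = base[mod][:, None]
        f = fu[mod][:, None]
        pair = np.concatenate([b, f], axis=1)
        disp = model.reg_nets[mod].forward(pair, train=train)
        warped, wcache = nn.warp3d(b, disp)
        seg_in.extend([warped, f])
        caches[mod] = (disp, warped, wcache, f)
    x = np.concatenate(seg_in, axis=1)
    logits = model.seg_net.forward(x, train=train)
    return logits, caches


def train_detector(
    cases: Sequence[LongitudinalCase], cfg: DetectionConfig, seed: int = 0
) -> DetectionModel:
    """End-to-end training: sum over modalities of the unsupervised
    registration loss + voxelwise cross-entropy against the new-lesion
    mask, Adam, 32^3/stride-16 patches with lesion-containing patches
    oversampled to half of each batch."""
    import warnings

    cfg = dataclasses.replace(cfg, seed=seed)
    model = build_detection_model(cfg)
    all_patches = []
    for case in cases:
        all_patches.extend(_case_patches(case, cfg))
    if not all_patches:
        raise ValueError("no training patches")
    pos_idx = [i for i, p in enumerate(all_patches) if p[3].any()]
    neg_idx = [i for i, p in enumerate(all_patches) if not p[3].any()]
    if not pos_idx:
        warnings.warn(
            "no case contains any lesion voxel; training on stable cases only",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    params = []
    for mod in cfg.modalities:
        params += model.reg_nets[mod].params()
    params += model.seg_net.params()
    opt = nn.Adam(params, lr=cfg.learning_rate)

    n_half = cfg.batch_size // 2
    for step in range(cfg.n_steps):
        if pos_idx and neg_idx:
            if cfg.batch_size == 1:
                # 50/50 oversampling degenerates to alternation
                pool = pos_idx if step % 2 == 0 else neg_idx
                ids = rng.choice(pool, size=1)
            else:
                ids = np.concatenate(
                    [
                        rng.choice(pos_idx, size=n_half),
                        rng.choice(neg_idx, size=cfg.batch_size - n_half),
                    ]
                )
        else:
            pool = pos_idx or neg_idx
            ids = rng.choice(pool, size=cfg.batch_size)
        batch = [all_patches[i] for i in ids]
        base = {
            m: np.stack([b[1][m] for b in batch]) for m in cfg.modalities
        }
        fu = {m: np.stack([b[2][m] for b in batch]) for m in cfg.modalities}
        gt = np.stack([b[3] for b in batch]).astype(np.int64)
        bmask = np.stack([b[4] for b in batch]).astype(np.float32)

        opt.zero_grad()
        logits, caches = _forward_batch(model, base, fu, train=True)

        if cfg.lesion_class_weight > 0:
            w_pos = cfg.lesion_class_weight
        else:
            frac = max(gt.mean(), 1e-6)
            w_pos = float(min(1.0 / frac, 200.0))
        ce, gce = nn.softmax_ce(logits, gt, np.array([1.0, w_pos], dtype=np.float32))
        gseg = model.seg_net.backward(gce.astype(np.float32))

        reg_total = 0.0
        ch = 0
        for mod in cfg.modalities:
            disp, warped, wcache, f = caches[mod]
            g_warped = gseg[:, ch : ch + 1]
            # appearance term: masked MSE between warped baseline and follow-up
            mse, gmse = nn.mse_loss(warped, f, weight=bmask[:, None])
            sm, gsm = nn.smoothness_penalty(disp)
            reg_total += mse + cfg.smoothness_weight * sm
            g_disp = nn.warp3d_backward(
                (g_warped + gmse).astype(np.float32), wcache
            )
            g_disp += cfg.smoothness_weight * gsm.astype(np.float32)
            model.reg_nets[mod].backward(g_disp)
            ch += 2  # skip the follow-up channel (input data, no params)
        opt.step()
        model.history["total"].append(ce + reg_total)
        model.history["ce"].append(ce)
        model.history["reg"].append(reg_total)
    model.provenance = {"seed": seed, "n_cases": len(cases)}
    return model


def predict_new_lesions(model: DetectionModel, case: LongitudinalCase) -> Volume:
    """Lesion-class probability volume on the follow-up grid (tiled,
    Hann-blended patch inference)."""
    cfg = model.cfg
    patches = _case_patches(case, cfg)
    ref = case.followup["FLAIR"]
    if not patches:
        return Volume(np.zeros(ref.shape, np.float32), ref.affine.copy(), ref.mask)
    preds = []
    for i in range(0, len(patches), 8):
        chunk = patches[i : i + 8]
        base = {m: np.stack([b[1][m] for b in chunk]) for m in cfg.modalities}
        fu = {m: np.stack([b[2][m] for b in chunk]) for m in cfg.modalities}
        logits, _ = _forward_batch(model, base, fu, train=False)
        mx = logits.max(axis=1, keepdims=True)
        ex = np.exp(logits - mx)
        prob = ex[:, 1] / ex.sum(axis=1)
        preds.extend((b[0], prob[j]) for j, b in enumerate(chunk))
    out = blend_patches(preds, ref.shape, cfg.patch_size)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    if ref.mask is not None:
        out[~ref.mask] = 0.0
    return Volume(out, ref.affine.copy(), ref.mask)


def postprocess(
    prob: Volume, threshold: float = 0.5, min_voxels: int = 3
) -> Volume:
    """Apply the inference rules: binarize at probability >= threshold
    (inclusive), 26-connectivity components, drop components smaller than
    ``min_voxels``; returns an integer-labeled component Volume."""
    binary = prob.data >= threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_voxels) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
    return Volume(labels.astype(np.int32), prob.affine.copy(), prob.mask)
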