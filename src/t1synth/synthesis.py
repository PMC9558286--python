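"""Cluster-conditioned 3D adversarial T1 synthesis.

The generator is a patchwise residual U-Net ("8 blocks": 4 encoder + 4
decoder residual blocks around a bottleneck) that maps the c-channel one-hot
cluster encoding of a FLAIR patch to a T1-contrast patch in [0, 1]; skip
connections merge by voxelwise summation. The discriminator is a 4-block
residual network scoring 32^3 patches as real or synthetic. Training
alternates discriminator and generator updates; the discriminator sees
smoothed real labels (1 - eps) and the generator combines the adversarial
term with an L1 reconstruction term against the real T1 patch (pix2pix
convention, default weight ratio 100:1).

Whole-volume inference tiles the volume into 32^3 patches at stride 16 and
blends overlapping predictions with a separable Hann window normalized to a
partition of unity, which suppresses patch-seam artifacts.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .clustering import ClusterMap, cluster_intensities, one_hot
from .volumes import LongitudinalCase, Volume


@dataclasses.dataclass
class GeneratorConfig:
    """Residual U-Net generator: ``n_blocks`` residual blocks total split
    evenly between encoder and decoder; summation skip merges; 3x3x3
    convolutions; stride-2 (2x2x2) pooling; sigmoid output."""

    in_channels: int = 7
    n_blocks: int = 8
    base_width: int = 8
    width_cap: int = 64

    def __post_init__(self) -> None:
        if self.n_blocks % 2:
            raise ValueError("n_blocks must split evenly into encoder/decoder")

    @property
    def depth(self) -> int:
        return self.n_blocks // 2


@dataclasses.dataclass
class DiscriminatorConfig:
    n_blocks: int = 4
    base_width: int = 8
    width_cap: int = 64


@dataclasses.dataclass
class SynthTrainConfig:
    patch_size: int = 32
    patch_stride: int = 16
    patches_per_volume: int = 0  # 0 = exhaustive lattice; else random sample
    label_smoothing: float = 0.1
    adv_weight: float = 1.0
    l1_weight: float = 100.0
    learning_rate: float = 2e-3
    n_steps: int = 200
    batch_size: int = 2
    min_brain_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_smoothing < 0.5):
            raise ValueError("label smoothing must lie in [0, 0.5)")
        if self.adv_weight < 0 or self.l1_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.adv_weight == 0 and self.l1_weight == 0:
            raise ValueError("at least one of adv_weight, l1_weight must be > 0")


# ---------------------------------------------------------------------------
# patch algebra


def patch_origins(dims: Sequence[int], size: int, stride: int) -> List[Tuple[int, int, int]]:
    """Origins of a regular stride lattice clipped to fit, padded with a
    final flush-to-edge origin per axis when the lattice would not cover
    the volume."""
    per_axis = []
    for d in dims:
        if size > d:
            raise ValueError(f"grid dim {d} smaller than patch size {size}")
        xs = list(range(0, d - size + 1, stride))
        if xs[-1] != d - size:
            xs.append(d - size)
        per_axis.append(xs)
    return [
        (z, y, x) for z in per_axis[0] for y in per_axis[1] for x in per_axis[2]
    ]


@dataclasses.dataclass
class PatchRecord:
    origin: Tuple[int, int, int]
    channels: np.ndarray  # (C, s, s, s)
    target: Optional[np.ndarray]  # (s, s, s) or None


def extract_patches(
    channels: np.ndarray,
    target: Optional[Volume],
    size: int = 32,
    stride: int = 16,
    mask: Optional[np.ndarray] = None,
    min_brain_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    n_random: int = 0,
) -> List[PatchRecord]:
    """Cut (C, D, H, W) channels (+ optional target volume) into patches.

    Origins lie on the stride lattice; with ``n_random`` > 0 that many
    origins are drawn uniformly from the lattice instead (sampled
    training). ``min_brain_fraction`` drops patches with too little brain.
    """
    channels = np.asarray(channels)
    if channels.ndim != 4:
        raise ValueError("channels must be (C, D, H, W)")
    dims = channels.shape[1:]
    if target is not None and target.shape != dims:
        raise ValueError("target grid does not match channels")
    origins = patch_origins(dims, size, stride)
    if n_random > 0:
        idx = rng.integers(0, len(origins), size=n_random)
        origins = [origins[i] for i in idx]
    out = []
    for oz, oy, ox in origins:
        sl = (slice(oz, oz + size), slice(oy, oy + size), slice(ox, ox + size))
        if mask is not None and min_brain_fraction > 0:
            if mask[sl].mean() < min_brain_fraction:
                continue
        out.append(
            PatchRecord(
                origin=(oz, oy, ox),
                channels=channels[(slice(None),) + sl],
                target=None if target is None else target.data[sl],
            )
        )
    return out


def hann_weight(size: int, floor: float = 0.05) -> np.ndarray:
    """Separable 3D Hann window with a small floor (so border voxels covered
    by a single patch keep nonzero weight before normalization)."""
    w1 = np.hanning(size + 2)[1:-1] + floor
    return (w1[:, None, None] * w1[None, :, None] * w1[None, None, :]).astype(np.float32)


def blend_patches(
    patches: Sequence[Tuple[Tuple[int, int, int], np.ndarray]],
    dims: Sequence[int],
    size: int,
) -> np.ndarray:
    """Weighted-average reassembly of (origin, patch) pairs.

    Accumulated Hann weights are normalized away, so the blending weights
    form a partition of unity: a constant field reassembles to itself.
    """
    acc = np.zeros(tuple(dims), dtype=np.float64)
    wacc = np.zeros(tuple(dims), dtype=np.float64)
    w = hann_weight(size).astype(np.float64)
    for (oz, oy, ox), p in patches:
        sl = (slice(oz, oz + size), slice(oy, oy + size), slice(ox, ox + size))
        acc[sl] += w * p
        wacc[sl] += w
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / wacc, 0.0)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# networks


def build_generator(cfg: GeneratorConfig, rng: np.random.Generator, patch_size: int = 32) -> nn.UNet3D:
    """(patch, c) -> (patch, 1) in [0, 1]; raises if the patch side does not
    survive ``depth`` halvings."""
    if patch_size % (2 ** cfg.depth):
        raise ValueError(
            f"patch size {patch_size} not divisible by 2^{cfg.depth}"
        )
    return nn.UNet3D(
        cin=cfg.in_channels,
        cout=1,
        base_width=cfg.base_width,
        depth=cfg.depth,
        rng=rng,
        final="sigmoid",
        width_cap=cfg.width_cap,
    )


def build_discriminator(cfg: DiscriminatorConfig, rng: np.random.Generator) -> nn.ResNetScorer:
    """Patch -> scalar real/fake logit."""
    return nn.ResNetScorer(
        cin=1,
        base_width=cfg.base_width,
        n_blocks=cfg.n_blocks,
        rng=rng,
        width_cap=cfg.width_cap,
    )


@dataclasses.dataclass
class SynthesisModel:
    """Trained synthesizer: network states + configs + training history."""

    generator: nn.UNet3D
    discriminator: Optional[nn.ResNetScorer]
    gcfg: GeneratorConfig
    dcfg: DiscriminatorConfig
    tcfg: SynthTrainConfig
    c: int
    history: Dict[str, List[float]]
    provenance: Dict[str, object] = dataclasses.field(default_factory=dict)

    def save(self, path) -> None:
        header = {
            "format": "t1synth-synthesis-v1",
            "c": self.c,
            "gcfg": dataclasses.asdict(self.gcfg),
            "dcfg": dataclasses.asdict(self.dcfg),
            "tcfg": dataclasses.asdict(self.tcfg),
            "history": self.history,
            "provenance": self.provenance,
            "has_discriminator": self.discriminator is not None,
        }
        arrays = {f"g_{i}": a for i, a in enumerate(self.generator.state())}
        if self.discriminator is not None:
            arrays.update(
                {f"d_{i}": a for i, a in enumerate(self.discriminator.state())}
            )
        buf = io.BytesIO()
        np.savez(buf, header=json.dumps(header), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path) -> "SynthesisModel":
        with np.load(Path(path), allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format") != "t1synth-synthesis-v1":
                raise ValueError("not a t1synth synthesis model file")
            gcfg = GeneratorConfig(**header["gcfg"])
            dcfg = DiscriminatorConfig(**header["dcfg"])
            tcfg = SynthTrainConfig(**header["tcfg"])
            rng = np.random.default_rng(0)  # shapes only; overwritten below
            gen = build_generator(gcfg, rng, tcfg.patch_size)
            gen.load_state([z[f"g_{i}"] for i in range(len(gen.state()))])
            disc = None
            if header["has_discriminator"]:
                disc = build_discriminator(dcfg, rng)
                disc.load_state([z[f"d_{i}"] for i in range(len(disc.state()))])
        return cls(
            generator=gen,
            discriminator=disc,
            gcfg=gcfg,
            dcfg=dcfg,
            tcfg=tcfg,
            c=header["c"],
            history={k: list(v) for k, v in header["history"].items()},
            provenance=header.get("provenance", {}),
        )


def _training_pairs(
    cases: Sequence[LongitudinalCase], c: int, tcfg: SynthTrainConfig, seed: int
) -> List[PatchRecord]:
    """Patch records from every (FLAIR, T1) image pair of every case and
    timepoint; the FLAIR is clustered and one-hot encoded."""
    rng = np.random.default_rng(seed)
    records: List[PatchRecord] = []
    for case in cases:
        for tp in (case.baseline, case.followup):
            if "FLAIR" not in tp or "T1" not in tp:
                continue
            flair, t1 = tp["FLAIR"], tp["T1"]
            cm = cluster_intensities(flair, c, smoothing=0, seed=seed)
            oh = one_hot(cm)
            records.extend(
                extract_patches(
                    oh,
                    t1,
                    size=tcfg.patch_size,
                    stride=tcfg.patch_stride,
                    mask=flair.get_mask(),
                    min_brain_fraction=tcfg.min_brain_fraction,
                    rng=rng,
                    n_random=tcfg.patches_per_volume,
                )
            )
    return records


def train_synthesizer(
    cases: Sequence[LongitudinalCase],
    c: int,
    gcfg: Optional[GeneratorConfig] = None,
    dcfg: Optional[DiscriminatorConfig] = None,
    tcfg: Optional[SynthTrainConfig] = None,
    seed: int = 0,
) -> SynthesisModel:
    """Adversarial training of the FLAIR-cluster -> T1 generator.

    Discriminator: BCE with smoothed real target (1 - eps) on real T1
    patches vs 0 on generated patches. Generator: adv_weight x (fool the
    discriminator toward 1) + l1_weight x mean |fake - real|. With
    adv_weight = 0 the procedure reduces to pure voxelwise regression and
    the discriminator is never built. Fully seeded and deterministic.
    """
    if len(cases) == 0:
        raise ValueError("empty case list")
    for case in cases:
        for tp in (case.baseline, case.followup):
            if "FLAIR" in tp and "T1" not in tp:
                raise ValueError(f"case {case.case_id}: missing T1 target")
    gcfg = gcfg or GeneratorConfig(in_channels=c)
    if gcfg.in_channels != c:
        gcfg = dataclasses.replace(gcfg, in_channels=c)
    dcfg = dcfg or DiscriminatorConfig()
    tcfg = tcfg or SynthTrainConfig(seed=seed)

    records = _training_pairs(cases, c, tcfg, seed)
    if not records:
        raise ValueError("no training patches extracted")

    rng = np.random.default_rng(seed)
    gen = build_generator(gcfg, rng, tcfg.patch_size)
    adversarial = tcfg.adv_weight > 0
    disc = build_discriminator(dcfg, rng) if adversarial else None
    g_opt = nn.Adam(gen.params(), lr=tcfg.learning_rate)
    d_opt = nn.Adam(disc.params(), lr=tcfg.learning_rate) if adversarial else None

    history: Dict[str, List[float]] = {"g_loss": [], "g_l1": [], "d_loss": []}
    real_target = 1.0 - tcfg.label_smoothing
    for step in range(tcfg.n_steps):
        idx = rng.integers(0, len(records), size=tcfg.batch_size)
        xb = np.stack([records[i].channels for i in idx]).astype(np.float32)
        yb = np.stack([records[i].target for i in idx]).astype(np.float32)[:, None]

        # --- discriminator update (real -> 1 - eps, fake -> 0)
        if adversarial:
            fake = gen.forward(xb, train=True)
            d_opt.zero_grad()
            lr_real, g_real = nn.bce_with_logits(
                disc.forward(yb, train=True), np.full(len(idx), real_target)
            )
            disc.backward(g_real.astype(np.float32))
            lr_fake, g_fake = nn.bce_with_logits(
                disc.forward(fake, train=True), np.zeros(len(idx))
            )
            disc.backward(g_fake.astype(np.float32))
            d_opt.step()
            history["d_loss"].append(lr_real + lr_fake)

        # --- generator update
        g_opt.zero_grad()
        fake = gen.forward(xb, train=True)
        grad = np.zeros_like(fake)
        l1, gl1 = nn.l1_loss(fake, yb)
        grad += tcfg.l1_weight * gl1
        g_loss = tcfg.l1_weight * l1
        if adversarial:
            ladv, gadv_logit = nn.bce_with_logits(
                disc.forward(fake, train=True), np.ones(len(idx))
            )
            grad += tcfg.adv_weight * disc.backward(gadv_logit.astype(np.float32))
            g_loss += tcfg.adv_weight * ladv
        gen.backward(grad.astype(np.float32))
        g_opt.step()
        history["g_loss"].append(g_loss)
        history["g_l1"].append(l1)

    return SynthesisModel(
        generator=gen,
        discriminator=disc,
        gcfg=gcfg,
        dcfg=dcfg,
        tcfg=tcfg,
        c=c,
        history=history,
        provenance={"seed": seed, "n_cases": len(cases)},
    )


def synthesize_t1(
    model: SynthesisModel, flair: Volume, cluster_map: ClusterMap
) -> Volume:
    """Whole-volume T1 synthesis by tiled, Hann-blended generator inference.

    The output shares the FLAIR grid, is restricted to the brain mask and
    clipped to [0, 1].
    """
    if cluster_map.c != model.c:
        raise ValueError(
            f"cluster count mismatch: map has c={cluster_map.c}, model c={model.c}"
        )
    size = model.tcfg.patch_size
    stride = model.tcfg.patch_stride
    oh = one_hot(cluster_map)
    recs = extract_patches(oh, None, size=size, stride=stride)
    preds = []
    for i in range(0, len(recs), 8):
        chunk = recs[i : i + 8]
        xb = np.stack([r.channels for r in chunk]).astype(np.float32)
        yb = model.generator.forward(xb, train=False)
        preds.extend((r.origin, yb[j, 0]) for j, r in enumerate(chunk))
    out = blend_patches(preds, flair.shape, size)
    mask = flair.get_mask()
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    out[~mask] = 0.0
    return Volume(out, flair.affine.copy(), mask.copy())
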