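"""Longitudinal dual-contrast brain phantoms with ground-truth new lesions.

The phantom is a parametric three-tissue brain: concentric deformed
ellipsoid shells (CSF outermost, then gray matter, white matter innermost)
with one-voxel partial-volume shells at the tissue interfaces, rendered in
two contrasts of the same anatomy:

* FLAIR-like: CSF dark, GM > WM, lesions hyperintense (brighter than WM);
* T1-like: WM bright, GM darker (inverted GM/WM contrast), lesions
  hypointense (darker than WM).

A longitudinal case renders both contrasts at two timepoints; the follow-up
anatomy carries additional spherical white-matter "new lesions" and the
baseline volumes are pushed through a small random rigid misalignment, so
the downstream registration and detection stages have real work to do.

Label codes
-----------
0 background, 1 CSF, 2 GM, 3 WM, 4 CSF/GM partial volume,
5 GM/WM partial volume, 6 new lesion.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LongitudinalCase, Volume, write_volume_with_mask

BACKGROUND, CSF, GM, WM, PV_CSF_GM, PV_GM_WM, LESION = range(7)

#: Per-label mean intensities. Lesions are hyperintense on FLAIR and
#: hypointense on T1; GM/WM contrast is inverted between the two.
DEFAULT_CONTRAST_FLAIR: Dict[int, float] = {
    BACKGROUND: 0.0,
    CSF: 0.10,
    GM: 0.60,
    WM: 0.45,
    PV_CSF_GM: 0.35,
    PV_GM_WM: 0.525,
    LESION: 0.90,
}
DEFAULT_CONTRAST_T1: Dict[int, float] = {
    BACKGROUND: 0.0,
    CSF: 0.10,
    GM: 0.45,
    WM: 0.75,
    PV_CSF_GM: 0.275,
    PV_GM_WM: 0.60,
    LESION: 0.35,
}


@dataclasses.dataclass
class PhantomSpec:
    """Study conditions for phantom generation.

    ``lesion_radius_vox`` has a minimum of 1.5 so every inserted sphere has
    at least 19 voxels, comfortably above the 3-voxel minimum-size rule the
    detector applies at inference.
    """

    dims: Tuple[int, int, int] = (64, 64, 64)
    n_tissues: int = 3
    contrast_flair: Dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_FLAIR)
    )
    contrast_t1: Dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_T1)
    )
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    n_new_lesions: Tuple[int, int] = (1, 3)
    lesion_radius_vox: Tuple[float, float] = (1.5, 3.0)
    misalign_translation_vox: Tuple[float, float] = (-3.0, 3.0)
    misalign_rotation_deg: Tuple[float, float] = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast_flair[LESION] <= self.contrast_flair[WM]:
            raise ValueError("FLAIR lesion intensity must exceed WM intensity")
        if self.contrast_t1[LESION] >= self.contrast_t1[WM]:
            raise ValueError("T1 lesion intensity must be below WM intensity")
        if self.lesion_radius_vox[0] < 1.0:
            raise ValueError("minimum lesion radius must be >= 1 voxel")
        if min(self.dims) < 32:
            raise ValueError("phantom dims must be >= 32 per axis")


def _smooth_field(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Zero-mean, unit-ish-amplitude smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    amp = np.max(np.abs(f))
    return f / amp if amp > 0 else f


def generate_anatomy(spec: PhantomSpec, seed: int) -> Volume:
    """Deterministic three-tissue anatomy with partial-volume shells.

    Returns an integer label Volume with the brain mask attached.
    """
    dims = np.asarray(spec.dims)
    if np.any(dims < 32):
        raise ValueError("dims too small to host all shells (need >= 32)")
    rng = np.random.default_rng(seed)
    center = (dims - 1) / 2.0
    semiaxes = dims * np.array([0.42, 0.40, 0.38])
    grid = np.indices(tuple(dims)).astype(np.float64)
    rho = np.sqrt(
        sum(((grid[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    )
    # smooth radial perturbation -> non-ellipsoidal but still star-shaped brain
    rho = rho * (1.0 + 0.12 * _smooth_field(tuple(dims), rng, sigma=8.0))

    labels = np.zeros(tuple(dims), dtype=np.int16)
    labels[rho < 1.0] = CSF
    labels[rho < 0.85] = GM
    labels[rho < 0.60] = WM

    # one-voxel partial-volume shells at the two tissue interfaces
    struct = ndimage.generate_binary_structure(3, 1)
    for a, b, pv in ((CSF, GM, PV_CSF_GM), (GM, WM, PV_GM_WM)):
        ma, mb = labels == a, labels == b
        border = (ndimage.binary_dilation(ma, struct) & mb) | (
            ndimage.binary_dilation(mb, struct) & ma
        )
        labels[border] = pv

    mask = labels > 0
    affine = np.eye(4)
    return Volume(labels, affine, mask)


def render_modality(
    labels: Volume,
    contrast: Dict[int, float],
    noise_sd: float,
    bias_amplitude: float,
    seed: int,
) -> Volume:
    """Render an intensity volume from a label volume.

    intensity = class mean x smooth multiplicative bias field + Gaussian
    noise, clipped to >= 0. ``bias_amplitude`` is the peak-to-peak range of
    the bias field (mean 1). The brain mask is copied from the labels.
    """
    lab = labels.data.astype(np.int64)
    present = np.unique(lab)
    missing = [int(p) for p in present if p not in contrast]
    if missing:
        raise ValueError(f"missing class(es) in contrast profile: {missing}")
    lut = np.zeros(int(lab.max()) + 1, dtype=np.float64)
    for k, v in contrast.items():
        if k <= lab.max():
            lut[k] = v
    img = lut[lab]

    rng = np.random.default_rng(seed)
    if bias_amplitude > 0:
        bias = 1.0 + (bias_amplitude / 2.0) * _smooth_field(lab.shape, rng, sigma=16.0)
        img = img * bias
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=lab.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)
    mask = labels.get_mask().copy()
    img[~mask] = np.clip(img[~mask], 0.0, None)
    return Volume(img, labels.affine.copy(), mask)


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= radius**2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def insert_new_lesions(
    anatomy: Volume, spec: PhantomSpec, rng: np.random.Generator
) -> Tuple[Volume, np.ndarray]:
    """Insert spherical new lesions strictly inside WM.

    Returns (follow-up anatomy, boolean new-lesion mask). Raises RuntimeError
    if a lesion cannot be placed without overlap after 100 attempts.
    """
    labels = anatomy.data.copy()
    lesion_mask = np.zeros(labels.shape, dtype=bool)
    n = int(rng.integers(spec.n_new_lesions[0], spec.n_new_lesions[1] + 1))
    wm = labels == WM
    wm_idx = np.argwhere(wm)
    for _ in range(n):
        placed = False
        for _attempt in range(100):
            radius = float(rng.uniform(*spec.lesion_radius_vox))
            c = wm_idx[rng.integers(len(wm_idx))]
            vox = c[None, :] + _sphere_offsets(radius)
            if np.any(vox < 0) or np.any(vox >= np.array(labels.shape)):
                continue
            vz, vy, vx = vox[:, 0], vox[:, 1], vox[:, 2]
            if not np.all(labels[vz, vy, vx] == WM):
                continue  # must lie strictly inside WM, no overlap with lesions
            labels[vz, vy, vx] = LESION
            lesion_mask[vz, vy, vx] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place requested lesion count inside WM after 100 attempts"
            )
    out = Volume(labels, anatomy.affine.copy(), anatomy.get_mask().copy())
    return out, lesion_mask


def _misalignment_matrix(
    spec: PhantomSpec, shape, rng: np.random.Generator
) -> np.ndarray:
    """Random small rigid voxel-space transform about the grid center."""
    t = rng.uniform(*spec.misalign_translation_vox, size=3)
    ang = np.deg2rad(rng.uniform(*spec.misalign_rotation_deg, size=3))

    def rot(axis, a):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
        return m

    R = rot(0, ang[0]) @ rot(1, ang[1]) @ rot(2, ang[2])
    center = (np.asarray(shape) - 1) / 2.0
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t + center - R @ center
    return M


def _apply_misalignment(vol: Volume, M: np.ndarray, order: int) -> Volume:
    """Resample vol through the voxel-space map M (output voxel -> input voxel
    via the inverse)."""
    Minv = np.linalg.inv(M)
    data = ndimage.affine_transform(
        vol.data.astype(np.float32),
        Minv[:3, :3],
        Minv[:3, 3],
        order=order,
        mode="constant",
        cval=0.0,
    ).astype(np.float32)
    mask = None
    if vol.mask is not None:
        mask = (
            ndimage.affine_transform(
                vol.mask.astype(np.float32),
                Minv[:3, :3],
                Minv[:3, 3],
                order=0,
                mode="constant",
                cval=0.0,
            )
            > 0.5
        )
    return Volume(data, vol.affine.copy(), mask)


def make_longitudinal_case(spec: PhantomSpec, case_seed: int) -> LongitudinalCase:
    """Generate one longitudinal phantom case.

    Follow-up anatomy = baseline anatomy + inserted WM new lesions; baseline
    volumes are resampled through a random small rigid misalignment. Both
    FLAIR and T1 contrasts are rendered at both timepoints.
    """
    ss = np.random.SeedSequence([spec.seed, case_seed])
    seeds = ss.generate_state(8)
    anatomy = generate_anatomy(spec, int(seeds[0]))
    rng = np.random.default_rng(int(seeds[1]))
    fu_anatomy, lesion_mask = insert_new_lesions(anatomy, spec, rng)

    followup = {
        "FLAIR": render_modality(
            fu_anatomy, spec.contrast_flair, spec.noise_sd, spec.bias_amplitude, int(seeds[2])
        ),
        "T1": render_modality(
            fu_anatomy, spec.contrast_t1, spec.noise_sd, spec.bias_amplitude, int(seeds[3])
        ),
    }
    base_native = {
        "FLAIR": render_modality(
            anatomy, spec.contrast_flair, spec.noise_sd, spec.bias_amplitude, int(seeds[4])
        ),
        "T1": render_modality(
            anatomy, spec.contrast_t1, spec.noise_sd, spec.bias_amplitude, int(seeds[5])
        ),
    }
    mis_rng = np.random.default_rng(int(seeds[6]))
    M = _misalignment_matrix(spec, spec.dims, mis_rng)
    baseline = {k: _apply_misalignment(v, M, order=1) for k, v in base_native.items()}

    gt = Volume(lesion_mask.astype(np.uint8), anatomy.affine.copy(), anatomy.get_mask().copy())
    return LongitudinalCase(
        case_id=f"case_{case_seed:04d}",
        baseline=baseline,
        followup=followup,
        new_lesion_mask=gt,
    )


CASE_FILES = {
    ("baseline", "FLAIR"): "baseline_flair.nii.gz",
    ("baseline", "T1"): "baseline_t1.nii.gz",
    ("followup", "FLAIR"): "followup_flair.nii.gz",
    ("followup", "T1"): "followup_t1.nii.gz",
}
GT_FILE = "new_lesions_mask.nii.gz"


def write_case(case: LongitudinalCase, case_dir) -> None:
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for (tp, mod), fname in CASE_FILES.items():
        vols = case.baseline if tp == "baseline" else case.followup
        if mod in vols:
            write_volume_with_mask(vols[mod], case_dir / fname)
    if case.new_lesion_mask is not None:
        write_volume_with_mask(case.new_lesion_mask, case_dir / GT_FILE)


def make_dataset(
    n_cases: int,
    spec: PhantomSpec,
    out_dir,
    seed: int,
    stable_fraction: float = 0.0,
) -> pd.DataFrame:
    """Write ``n_cases`` phantom cases plus a ``manifest.tsv``.

    ``stable_fraction`` of the cases (rounded down, taken from the end) are
    generated with no new lesions, emulating stable patients. Case seeds are
    derived deterministically from the master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n_stable = int(n_cases * stable_fraction)
    for i in range(n_cases):
        case_seed = seed * 10000 + i
        cspec = spec
        if i >= n_cases - n_stable:
            cspec = dataclasses.replace(spec, n_new_lesions=(0, 0))
        case = make_longitudinal_case(cspec, case_seed)
        case_dir = out_dir / case.case_id
        write_case(case, case_dir)
        n_les = int(ndimage.label(case.new_lesion_mask.data > 0, np.ones((3, 3, 3)))[1])
        rows.append(
            {
                "case_id": case.case_id,
                "path": case.case_id,
                "n_lesions": n_les,
                "seed": case_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def load_case(case_dir, case_id: Optional[str] = None) -> LongitudinalCase:
    """Load a phantom case directory written by :func:`write_case`."""
    from .volumes import read_volume_with_mask

    case_dir = Path(case_dir)
    baseline, followup = {}, {}
    for (tp, mod), fname in CASE_FILES.items():
        p = case_dir / fname
        if p.exists():
            vol = read_volume_with_mask(p)
            (baseline if tp == "baseline" else followup)[mod] = vol
    gt = None
    if (case_dir / GT_FILE).exists():
        gt = read_volume_with_mask(case_dir / GT_FILE)
    return LongitudinalCase(
        case_id=case_id or case_dir.name,
        baseline=baseline,
        followup=followup,
        new_lesion_mask=gt,
    )


def dataset_hash(out_dir) -> str:
    """SHA-256 over the manifest, for run-record provenance."""
    data = (Path(out_dir) / "manifest.tsv").read_bytes()
    return hashlib.sha256(data).hexdigest()
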