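"""Preprocessing chain: affine registration to a reference space with
transform concatenation, skull stripping, and [0, 1] intensity
normalization.

Registration is mono-modal (same contrast at both timepoints), so the
similarity objective is the masked mean-squared intensity difference,
minimized by multi-resolution Powell search over translation / rigid /
affine parameters. The follow-up image receives a single transform to the
template grid; the baseline receives the concatenation of baseline->follow-up
and follow-up->template, so it is interpolated only once.

The built-in skull stripper (Otsu threshold + largest connected component +
morphological closing) is intentionally simple; a precomputed mask can be
supplied instead and is used verbatim (plug-in contract).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_multiotsu, threshold_otsu

from .volumes import Volume

DOF_PARAMS = {"translation": 3, "rigid": 6, "affine": 12}


@dataclasses.dataclass
class AffineTransform:
    """A forward world-coordinate map from a moving space to a fixed space.

    ``matrix`` is 4x4 homogeneous; ``fixed_space`` names the target grid
    (used only to catch accidental mis-composition).
    """

    matrix: np.ndarray
    fixed_space: str = "fixed"
    moving_space: str = "moving"
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-10):
            raise ValueError("last row of an affine transform must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform matrix must be invertible")

    @classmethod
    def identity(cls, space: str = "fixed") -> "AffineTransform":
        return cls(np.eye(4), fixed_space=space, moving_space=space)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix),
            fixed_space=self.moving_space,
            moving_space=self.fixed_space,
        )


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """The transform 'apply a, then b' (a: X->Y, b: Y->Z gives X->Z)."""
    if a.fixed_space != b.moving_space:
        raise ValueError(
            f"space mismatch: a maps into {a.fixed_space!r} but b maps from "
            f"{b.moving_space!r}"
        )
    return AffineTransform(
        b.matrix @ a.matrix, fixed_space=b.fixed_space, moving_space=a.moving_space
    )


def resample(
    vol: Volume,
    t: AffineTransform,
    target_grid: Volume,
    interpolation: str = "linear",
) -> Volume:
    """Sample ``vol`` on ``target_grid`` through the world-space map ``t``.

    ``t`` maps vol's world space into the target's world space. Linear
    interpolation for intensities, nearest for labels/masks; out-of-field
    voxels are set to 0.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = 1 if interpolation == "linear" else 0
    # output voxel -> output world -> (t^-1) moving world -> moving voxel
    M = np.linalg.inv(vol.affine) @ np.linalg.inv(t.matrix) @ target_grid.affine
    if abs(np.linalg.det(M[:3, :3])) < 1e-12:
        raise ValueError("singular resampling transform")
    data = ndimage.affine_transform(
        vol.data.astype(np.float32),
        M[:3, :3],
        M[:3, 3],
        output_shape=target_grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
    ).astype(np.float32)
    mask = None
    if vol.mask is not None:
        mask = (
            ndimage.affine_transform(
                vol.mask.astype(np.float32),
                M[:3, :3],
                M[:3, 3],
                output_shape=target_grid.shape,
                order=0,
                mode="constant",
                cval=0.0,
            )
            > 0.5
        )
    return Volume(data, target_grid.affine.copy(), mask)


def _params_to_matrix(params: np.ndarray, dof: str, center_world: np.ndarray) -> np.ndarray:
    """Build a world-space 4x4 from the parameter vector.

    Layout: [tx ty tz] (+ [rx ry rz] radians) (+ [sx sy sz shxy shxz shyz]).
    Rotation/scale/shear act about ``center_world``.
    """
    t = params[:3]
    A = np.eye(3)
    if dof in ("rigid", "affine"):
        rx, ry, rz = params[3:6]

        def rot(axis, ang):
            c, s = np.cos(ang), np.sin(ang)
            m = np.eye(3)
            i, j = [k for k in range(3) if k != axis]
            m[i, i] = c
            m[j, j] = c
            m[i, j] = -s
            m[j, i] = s
            return m

        A = rot(0, rx) @ rot(1, ry) @ rot(2, rz)
    if dof == "affine":
        sx, sy, sz, shxy, shxz, shyz = params[6:12]
        S = np.diag([np.exp(sx), np.exp(sy), np.exp(sz)])
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = shxy, shxz, shyz
        A = A @ S @ Sh
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = t + center_world - A @ center_world
    return M


def registration_objective(
    moving: Volume, fixed: Volume, t: AffineTransform
) -> float:
    """Masked mean-squared intensity difference after applying ``t``."""
    warped = resample(moving, t, fixed, interpolation="linear")
    fmask = fixed.get_mask()
    wmask = warped.mask if warped.mask is not None else np.ones(fixed.shape, bool)
    m = fmask & wmask
    if not m.any():
        raise ValueError("no overlap between moving and fixed masks")
    diff = warped.data[m].astype(np.float64) - fixed.data[m].astype(np.float64)
    return float(np.mean(diff**2))


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    data = ndimage.zoom(vol.data.astype(np.float32), 1.0 / factor, order=1)
    aff = vol.affine.copy()
    aff[:3, :3] *= factor
    mask = None
    if vol.mask is not None:
        mask = ndimage.zoom(vol.mask.astype(np.float32), 1.0 / factor, order=0) > 0.5
    return Volume(data, aff, mask)


def affine_register(
    moving: Volume,
    fixed: Volume,
    dof: str = "rigid",
    levels: Tuple[int, ...] = (4, 2),
) -> AffineTransform:
    """Estimate the world-space transform aligning ``moving`` onto ``fixed``.

    Multi-resolution (coarse-to-fine) Powell minimization of the masked MSE.
    Deterministic given its inputs. If the optimizer fails to reduce the
    objective below its identity-transform value, the identity is returned
    with ``converged=False``.
    """
    if dof not in DOF_PARAMS:
        raise ValueError(f"dof must be one of {sorted(DOF_PARAMS)}")
    mmask = moving.get_mask()
    fmask = fixed.get_mask()
    if not (mmask.any() and fmask.any()):
        raise ValueError("no overlap: empty mask")
    # quick disjointness check in the fixed grid at identity
    ident = AffineTransform.identity()
    probe = resample(
        Volume(mmask.astype(np.float32), moving.affine, mmask), ident, fixed, "nearest"
    )
    if not (probe.data.astype(bool) & fmask).any():
        raise ValueError("no overlap between moving and fixed masks")

    nparams = DOF_PARAMS[dof]
    params = np.zeros(nparams)
    center_vox = (np.asarray(fixed.shape) - 1) / 2.0
    center_world = (fixed.affine @ np.append(center_vox, 1.0))[:3]

    for factor in levels:
        mv = _downsample(moving, factor)
        fx = _downsample(fixed, factor)

        def cost(p):
            try:
                t = AffineTransform(_params_to_matrix(p, dof, center_world))
                return registration_objective(mv, fx, t)
            except ValueError:
                return 1e12

        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options={"xtol": 1e-2, "ftol": 1e-6, "maxiter": 20},
        )
        params = res.x

    final = AffineTransform(_params_to_matrix(params, dof, center_world))
    before = registration_objective(moving, fixed, ident)
    after = registration_objective(moving, fixed, final)
    if after > before:
        ident.converged = False
        return ident
    return final


def skull_strip(vol: Volume, precomputed_mask: Optional[np.ndarray] = None) -> Volume:
    """Brain mask as a {0,1} Volume.

    Built-in: Otsu threshold on intensities, largest connected component,
    binary closing. A ``precomputed_mask`` (e.g. from an external tool) is
    accepted verbatim instead.
    """
    if precomputed_mask is not None:
        m = np.asarray(precomputed_mask) > 0
        if m.shape != vol.shape:
            raise ValueError("precomputed mask shape mismatch")
        return Volume(m.astype(np.uint8), vol.affine.copy())
    data = vol.data.astype(np.float32)
    if not np.any(data > 0) or np.ptp(data) == 0:
        raise ValueError("empty mask: volume has no foreground intensities")
    # smooth first so background speckle separates from dark tissue; the
    # lowest three-class Otsu threshold sits at the air/CSF boundary but
    # overestimates it when the two overlap, so back off toward air
    smoothed = ndimage.gaussian_filter(data, 2.0)
    try:
        thr = 0.6 * threshold_multiotsu(smoothed, classes=3)[0]
    except ValueError:
        thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise ValueError("empty mask after thresholding")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("empty mask after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    closed = ndimage.binary_closing(largest, structure=np.ones((3, 3, 3)), iterations=2)
    closed = ndimage.binary_fill_holes(closed)
    return Volume(closed.astype(np.uint8), vol.affine.copy())


def normalize01(vol: Volume, pct_lo: float = 1.0, pct_hi: float = 99.0) -> Volume:
    """Map in-mask intensities to [0, 1] by percentile-clipped min-max.

    Out-of-mask voxels are set to 0. Raises on a constant in-mask image.
    """
    if vol.mask is None or not vol.mask.any():
        raise ValueError("normalize01 requires a non-empty mask")
    vals = vol.data[vol.mask].astype(np.float64)
    p_lo, p_hi = np.percentile(vals, [pct_lo, pct_hi])
    if p_hi <= p_lo:
        raise ValueError("constant in-mask image: cannot normalize")
    out = (vol.data.astype(np.float64) - p_lo) / (p_hi - p_lo)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    out[~vol.mask] = 0.0
    return Volume(out, vol.affine.copy(), vol.mask.copy())


def preprocess_pair(
    baseline: Volume,
    followup: Volume,
    template: Optional[Volume] = None,
    dof: str = "rigid",
) -> Tuple[Volume, Volume, AffineTransform]:
    """Full chain for one modality pair.

    Follow-up is registered to the template (identity when ``template`` is
    None, i.e. the follow-up grid *is* the reference); the baseline transform
    is the concatenation baseline->follow-up then follow-up->template, so the
    baseline is interpolated once. Returns (baseline', followup', t_base).
    """
    t_b2f = affine_register(baseline, followup, dof=dof)
    t_b2f.fixed_space = "followup"
    t_b2f.moving_space = "baseline"
    if template is None:
        t_f2t = AffineTransform.identity("followup")
        target = followup
        fu_out = followup.copy()
    else:
        t_f2t = affine_register(followup, template, dof=dof)
        t_f2t.fixed_space = "template"
        t_f2t.moving_space = "followup"
        target = template
        fu_out = resample(followup, t_f2t, template, "linear")
    t_base = compose(t_b2f, t_f2t)
    base_out = resample(baseline, t_base, target, "linear")
    return base_out, fu_out, t_base
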