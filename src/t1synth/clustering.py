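"""Intensity clustering of the T2-FLAIR volume into c clusters.

The cluster map is the conditioning input of the T1 synthesizer: in-brain
FLAIR intensities are fit with a c-component Gaussian mixture (seeded
k-means++ initialization, best of 5 restarts), optionally followed by a few
iterations of spatial mode filtering of the hard label map. Labels are
re-indexed so cluster means ascend, which pins the semantics of each
one-hot channel (channel 0 = darkest tissue, typically CSF) across images
— a prerequisite for the synthesis model to transfer between cases.

c = 3 corresponds to CSF / gray matter / white matter; c = 5 adds the two
partial-volume shells between them; larger c (7, 9) has no direct
biological reading but yields a finer intensity quantization for the
synthesis conditioning.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .volumes import Volume

BACKGROUND_SENTINEL = -1
DEFAULT_CLUSTER_COUNTS = (3, 5, 7, 9)


@dataclasses.dataclass
class ClusterMap:
    """Hard tissue clustering of a FLAIR volume.

    ``labels`` holds values 0..c-1 inside the brain mask and
    ``BACKGROUND_SENTINEL`` outside; ``means`` are per-cluster mean
    intensities in strictly ascending order; ``mixing`` the component
    weights in the same order.
    """

    labels: Volume
    c: int
    means: np.ndarray
    mixing: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.means) != self.c or len(self.mixing) != self.c:
            raise ValueError("means/mixing must have length c")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("cluster means must be strictly increasing")
        lab = self.labels.data
        inside = lab != BACKGROUND_SENTINEL
        present = np.unique(lab[inside])
        if len(present) and (present.min() < 0 or present.max() >= self.c):
            raise ValueError("labels must lie in 0..c-1 inside the mask")
        for k in range(self.c):
            if not np.any(lab == k):
                raise ValueError(f"cluster {k} is empty")

    @property
    def mask(self) -> np.ndarray:
        return self.labels.data != BACKGROUND_SENTINEL


def _mode_filter(labels: np.ndarray, mask: np.ndarray, c: int, iterations: int) -> np.ndarray:
    """Majority vote of the 3x3x3 neighborhood, restricted to the mask."""
    out = labels.copy()
    for _ in range(iterations):
        counts = np.empty((c,) + labels.shape, dtype=np.float32)
        for k in range(c):
            counts[k] = ndimage.uniform_filter(
                ((out == k) & mask).astype(np.float32), size=3, mode="constant"
            )
        new = np.argmax(counts, axis=0).astype(out.dtype)
        # a cluster may not be erased entirely by smoothing
        if all(np.any(new[mask] == k) for k in range(c)):
            out[mask] = new[mask]
    return out


def cluster_intensities(
    vol: Volume,
    c: int,
    smoothing: int = 0,
    seed: int = 0,
    n_init: int = 5,
    fit_subsample: int = 30000,
) -> ClusterMap:
    """Cluster in-mask intensities into ``c`` components.

    EM Gaussian mixture with seeded k-means++ initialization (best of
    ``n_init`` restarts), hard labels re-indexed by ascending mean, then
    ``smoothing`` iterations of spatial mode filtering inside the mask.
    The mixture is fit on a seeded subsample of ``fit_subsample`` in-mask
    voxels when more are present (a 1-D mixture is estimated to ample
    precision from tens of thousands of samples); assignment always covers
    every voxel. Set ``fit_subsample=0`` to fit on all voxels.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if c not in DEFAULT_CLUSTER_COUNTS:
        warnings.warn(
            f"c={c} is outside the usual {{3,5,7,9}} options", stacklevel=2
        )
    mask = vol.get_mask()
    if not mask.any():
        raise ValueError("empty mask")
    x = vol.data[mask].astype(np.float64).reshape(-1, 1)
    n_distinct = len(np.unique(x))
    if n_distinct < c:
        raise ValueError(
            f"fewer distinct in-mask intensities ({n_distinct}) than clusters ({c})"
        )
    gm = GaussianMixture(
        n_components=c,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-8,
        max_iter=300,
    )
    if fit_subsample and len(x) > fit_subsample:
        sub = np.random.default_rng(seed).choice(len(x), fit_subsample, replace=False)
        gm.fit(x[sub])
    else:
        gm.fit(x)
    raw_labels = gm.predict(x)
    means = gm.means_.ravel()
    order = np.argsort(means)
    rank = np.empty(c, dtype=np.int64)
    rank[order] = np.arange(c)
    labels_in = rank[raw_labels]
    means_sorted = means[order]
    mixing_sorted = gm.weights_.ravel()[order]
    if np.any(np.diff(means_sorted) <= 0):
        raise ValueError("degenerate mixture: coincident component means")

    lab = np.full(vol.shape, BACKGROUND_SENTINEL, dtype=np.int16)
    lab[mask] = labels_in
    if smoothing > 0:
        lab_nonneg = np.where(mask, lab, 0).astype(np.int16)
        sm = _mode_filter(lab_nonneg, mask, c, int(smoothing))
        lab = np.where(mask, sm, BACKGROUND_SENTINEL).astype(np.int16)
    for k in range(c):
        if not np.any(lab == k):
            raise ValueError(f"cluster {k} empty after smoothing")
    label_vol = Volume(lab, vol.affine.copy(), mask.copy())
    return ClusterMap(labels=label_vol, c=c, means=means_sorted, mixing=mixing_sorted)


def from_label_volume(labels: Volume, intensities: Optional[Volume] = None) -> ClusterMap:
    """Wrap an externally computed hard label map (e.g. genuine FSL FAST
    output) as a ClusterMap; labels are re-indexed by ascending mean of
    ``intensities`` when given, else assumed already canonical."""
    mask = labels.get_mask()
    lab = labels.data.astype(np.int16).copy()
    lab[~mask] = BACKGROUND_SENTINEL
    ids = np.unique(lab[mask])
    c = len(ids)
    remap = {int(v): i for i, v in enumerate(sorted(ids))}
    flat = lab[mask]
    lab[mask] = np.vectorize(remap.get)(flat)
    if intensities is not None:
        means = np.array(
            [intensities.data[(lab == k) & mask].mean() for k in range(c)]
        )
        order = np.argsort(means)
        rank = np.empty(c, dtype=np.int64)
        rank[order] = np.arange(c)
        lab[mask] = rank[lab[mask]]
        means = means[order]
    else:
        means = np.arange(c, dtype=float)
    mixing = np.array([(lab[mask] == k).mean() for k in range(c)])
    return ClusterMap(
        labels=Volume(lab, labels.affine.copy(), mask), c=c, means=means, mixing=mixing
    )


def one_hot(cm: ClusterMap) -> np.ndarray:
    """(c, D, H, W) float32 indicator stack; channels sum to 1 inside the
    mask and are all 0 outside."""
    lab = cm.labels.data
    mask = cm.mask
    out = np.zeros((cm.c,) + lab.shape, dtype=np.float32)
    for k in range(cm.c):
        out[k][(lab == k) & mask] = 1.0
    return out
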