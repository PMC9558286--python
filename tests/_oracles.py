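"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np
from scipy.stats import rankdata


def brute_force_match(pred: np.ndarray, gt: np.ndarray):
    """All-pairs voxel-intersection lesion matching."""
    pred_ids = [i for i in np.unique(pred) if i > 0]
    gt_ids = [i for i in np.unique(gt) if i > 0]
    tp = sum(1 for g in gt_ids if any(((gt == g) & (pred == p)).any() for p in pred_ids))
    fn = len(gt_ids) - tp
    fp = sum(
        1 for p in pred_ids if not any(((pred == p) & (gt == g)).any() for g in gt_ids)
    )
    return tp, fp, fn


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """26-connectivity components by explicit stack-based flood fill."""
    mask = mask.astype(bool)
    out = np.zeros(mask.shape, np.int32)
    nxt = 1
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if out[start]:
            continue
        stack = [start]
        out[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if (
                    all(0 <= q[i] < mask.shape[i] for i in range(3))
                    and mask[q]
                    and not out[q]
                ):
                    out[q] = nxt
                    stack.append(q)
        nxt += 1
    return out


def exact_signed_rank_p(diffs) -> float:
    """Two-sided signed-rank p by exhaustive 2^n sign enumeration."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ew = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - ew) >= abs(w_obs - ew) - 1e-12:
            count += 1
    return count / 2**n
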