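"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (exhaustive search, all-pairs scans,
textbook union-find) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def otsu_exhaustive(img: np.ndarray) -> tuple[int, float]:
    """Best threshold by direct between-class variance search over all levels.

    Foreground = pixels > t.  Returns (threshold, variance); ties break to
    the lowest level.
    """
    vals = np.asarray(img).ravel().astype(np.float64)
    best_t, best_v = 0, -1.0
    for t in range(255):
        fg = vals > t
        bg = ~fg
        if not fg.any() or not bg.any():
            continue
        w0, w1 = bg.mean(), fg.mean()
        v = w0 * w1 * (vals[bg].mean() - vals[fg].mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t, best_v


def distance_all_pairs(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance transform by scanning every background pixel."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        out[mask] = np.inf
        return out
    for r, c in np.argwhere(mask):
        d = np.hypot(bg[:, 0] - r, bg[:, 1] - c)
        out[r, c] = d.min()
    return out


def label_union_find(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Connected-component labeling by union-find over pixel pairs."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            parent.setdefault((r, c), (r, c))
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    parent.setdefault((rr, cc), (rr, cc))
                    union((r, c), (rr, cc))

    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    roots: dict = {}
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                root = find((r, c))
                if root not in roots:
                    roots[root] = next_label
                    next_label += 1
                labels[r, c] = roots[root]
    return labels


def filter_direct(candidates, max_length, max_area_ratio):
    """One-line acceptance rule: L < L_T and A1/A2 < R_a, both strict."""
    return [
        c
        for c in candidates
        if c.length < max_length and c.area_large / c.area_small < max_area_ratio
    ]


def convolve_direct(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 2-D convolution with reflect padding, nested loops."""
    img = np.asarray(img, dtype=np.float64)
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(img)
    flipped = kernel[::-1, ::-1]
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = (padded[r : r + kh, c : c + kw] * flipped).sum()
    return out
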