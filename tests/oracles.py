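"""Independent oracle implementations used only by the test-suite.

These deliberately share no code with the package: the Dijkstra here walks an
explicit adjacency structure with a binary heap, the threshold oracle is an
exhaustive search over all cut points, and the histogram-matching oracle is a
direct CDF table lookup.
"""

from __future__ import annotations

import heapq
from typing import Tuple

import numpy as np


def dijkstra_length(
    mask: np.ndarray,
    p: Tuple[int, int],
    q: Tuple[int, int],
    spacing: Tuple[float, float] = (1.0, 1.0),
) -> float:
    """Shortest 8-connected path cost from p to q inside a boolean mask."""
    sy, sx = spacing
    h, w = mask.shape
    moves = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            moves.append((dr, dc, ((dr * sy) ** 2 + (dc * sx) ** 2) ** 0.5))
    dist = {tuple(p): 0.0}
    heap = [(0.0, tuple(p))]
    target = tuple(q)
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if (r, c) == target:
            return d
        if d > dist.get((r, c), np.inf):
            continue
        for dr, dc, wgt in moves:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                nd = d + wgt
                if nd < dist.get((nr, nc), np.inf):
                    dist[(nr, nc)] = nd
                    heapq.heappush(heap, (nd, (nr, nc)))
    return np.inf


def exhaustive_two_means_cut(hist: np.ndarray) -> int:
    """Cut point (bins <= cut vs > cut) minimizing within-class squared deviation."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size, dtype=float)
    best_cut, best_cost = 0, np.inf
    for t in range(hist.size - 1):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        cost = 0.0
        for part, lv in ((lo, levels[: t + 1]), (hi, levels[t + 1 :])):
            wsum = part.sum()
            if wsum == 0:
                continue
            mu = (part * lv).sum() / wsum
            cost += (part * (lv - mu) ** 2).sum()
        if cost < best_cost:
            best_cost, best_cut = cost, t
    return best_cut


def cdf_inverse_lookup(src_hist: np.ndarray, ref_hist: np.ndarray, level: int) -> int:
    """Histogram-matching map for one gray level by direct CDF tables."""
    src_cdf = np.cumsum(src_hist) / np.sum(src_hist)
    ref_cdf = np.cumsum(ref_hist) / np.sum(ref_hist)
    target = src_cdf[level]
    for u in range(256):
        if ref_cdf[u] >= target - 1e-12:
            return u
    return 255


def icc21_mean_squares(x: np.ndarray) -> float:
    """ICC(2,1) by explicit ANOVA mean-squares arithmetic (scalar loops)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_connected_curve(
    rng: np.random.Generator, shape=(100, 100), n_steps: int = 150
) -> Tuple[np.ndarray, Tuple[int, int], Tuple[int, int]]:
    """A random connected 8-neighbor walk mask with its start/end pixels."""
    h, w = shape
    r, c = int(rng.integers(h // 4, 3 * h // 4)), int(rng.integers(w // 4, 3 * w // 4))
    mask = np.zeros(shape, dtype=bool)
    mask[r, c] = True
    start = (r, c)
    for _ in range(n_steps):
        dr, dc = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        nr, nc = min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)
        r, c = nr, nc
        mask[r, c] = True
    end = (r, c)
    return mask, start, end
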