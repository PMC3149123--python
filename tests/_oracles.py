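"""Brute-force reference implementations used only by the tests.

These are deliberately naive and independent of the library code paths they
check: BFS flood fill for connected components, an exhaustive 256-threshold
between-class-variance scan for Otsu, and an exhaustive window scan for
threshold-run finding.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean mask via breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp = set()
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                comp.add((y, x))
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(comp)
    return components


def otsu_exhaustive(data: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by exhaustive scan of all histogram-bin candidates.

    Returns the bin center maximizing the between-class variance
    w0 * w1 * (mu0 - mu1)^2 over the 256-bin histogram of the data range.
    """
    data = np.asarray(data, dtype=float).ravel()
    hist, edges = np.histogram(data, bins=nbins, range=(data.min(), data.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_sigma, best_thr = -1.0, centers[0]
    total = hist.sum()
    for t in range(1, nbins):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * centers[:t]).sum() / w0
        mu1 = (hist[t:] * centers[t:]).sum() / w1
        sigma = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_thr = sigma, centers[t - 1]
    return float(best_thr)


def otsu_objective(data: np.ndarray, thr: float, nbins: int = 256) -> float:
    """Between-class variance achieved by splitting the histogram at thr."""
    data = np.asarray(data, dtype=float).ravel()
    hist, edges = np.histogram(data, bins=nbins, range=(data.min(), data.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    left = centers <= thr
    w0, w1 = hist[left].sum(), hist[~left].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    total = hist.sum()
    mu0 = (hist[left] * centers[left]).sum() / w0
    mu1 = (hist[~left] * centers[~left]).sum() / w1
    return float((w0 / total) * (w1 / total) * (mu0 - mu1) ** 2)


def runs_exhaustive(z: np.ndarray, tau: float) -> list[tuple[int, int]]:
    """All maximal contiguous windows with every value above tau.

    Checks every contiguous window of the array and keeps those that are
    entirely above tau and cannot be extended on either side.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    runs = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not np.all(z[i:j] > tau):
                continue
            left_max = i == 0 or z[i - 1] <= tau
            right_max = j == n or z[j] <= tau
            if left_max and right_max:
                runs.append((i, j))
    return sorted(set(runs))
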