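"""Independent brute-force oracles and small utilities shared by the tests.

These deliberately re-derive each quantity from its definition (explicit
loops over the distance multiset, explicit kernel evaluation, flood fill)
so they stay independent of the library's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def adk_brute(counts: np.ndarray, k: int) -> np.ndarray:
    """O(N^2) ADK from the definition: per positive pixel, enumerate the full
    neighbor-count distance multiset (c-1 zeros for its own counts, full
    multiplicity for every other positive pixel) and average the k smallest."""
    counts = np.asarray(counts)
    out = np.full(counts.shape, np.nan, dtype=float)
    positions = [tuple(p) for p in np.argwhere(counts > 0)]
    for (i, j) in positions:
        dists: list[float] = []
        for (a, b) in positions:
            mult = int(counts[a, b]) - (1 if (a, b) == (i, j) else 0)
            dists.extend([math.hypot(i - a, j - b)] * mult)
        dists.sort()
        out[i, j] = sum(dists[:k]) / k if len(dists) >= k else math.inf
    return out


def blur_brute(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Direct convolution with the radial Gaussian kernel evaluated at
    integer offsets within the square window of half-width ceil(3*sigma),
    zero outside the image."""
    arr = np.asarray(arr, dtype=float)
    r = math.ceil(3 * sigma)
    h, w = arr.shape
    out = np.zeros_like(arr)
    norm = 2.0 * math.pi * sigma**2
    for i in range(h):
        for j in range(w):
            s = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    a, b = i - di, j - dj
                    if 0 <= a < h and 0 <= b < w:
                        s += arr[a, b] * math.exp(-(di * di + dj * dj) / (2.0 * sigma**2)) / norm
            out[i, j] = s
    return out


def flood_fill_objects(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by breadth-first flood fill, in order of their
    first row-major pixel."""
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    seen = np.zeros_like(mask)
    objects = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                queue = [(i, j)]
                seen[i, j] = True
                while queue:
                    a, b = queue.pop()
                    comp.add((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if 0 <= x < h and 0 <= y < w and mask[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                queue.append((x, y))
                objects.append(comp)
    return objects


def worked_example_image() -> np.ndarray:
    """The printed 5-nearest-counts configuration: a center pixel of 2
    counts, 1 count one pixel to its right, 3 counts two pixels above."""
    img = np.zeros((7, 7), dtype=np.uint32)
    img[3, 3] = 2
    img[3, 4] = 1
    img[1, 3] = 3
    return img


def valley_threshold(finite_adk: np.ndarray, bins: int = 40) -> float:
    """Denoising threshold at the valley of a bimodal ADK histogram: smooth
    the histogram, start at the (signal) peak, and walk right to the first
    bin where the counts stop falling after dropping well below the peak."""
    counts, edges = np.histogram(finite_adk, bins=bins)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts, kernel, mode="same")
    peak = int(np.argmax(smooth))
    for i in range(peak + 1, len(smooth) - 1):
        if smooth[i] < 0.25 * smooth[peak] and smooth[i] <= smooth[i + 1]:
            return float(edges[i + 1])
    return float(edges[peak + 1])
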