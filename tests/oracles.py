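"""Naive brute-force reference implementations used as test oracles.

Every function here enumerates neighborhoods pixel by pixel with clamped
(replicate) indexing and stays deliberately independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def finish(v: float, eight_bit: bool) -> float:
    if eight_bit:
        return min(max(round_half_up(v), 0.0), 255.0)
    return v


def _clamped(a: np.ndarray, i: int, j: int) -> float:
    h, w = a.shape
    return a[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]


def brute_normalize(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    out = np.zeros_like(a, dtype=float)
    if hi == lo:
        return out
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            out[i, j] = round_half_up((a[i, j] - lo) * 255.0 / (hi - lo))
    return out


def brute_gaussian(a: np.ndarray, sigma: float, eight_bit=True) -> np.ndarray:
    r = int(np.ceil(3.0 * sigma))
    k1 = np.array(
        [math.exp(-(d * d) / (2.0 * sigma * sigma)) for d in range(-r, r + 1)]
    )
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    out = np.zeros_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    acc += kernel[di + r, dj + r] * _clamped(a, i + di, j + dj)
            out[i, j] = finish(acc, eight_bit)
    return out


SOBEL_X = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]


def brute_sobel(a: np.ndarray, eight_bit=True) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            gx = gy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    v = _clamped(a, i + di, j + dj)
                    gx += SOBEL_X[di + 1][dj + 1] * v
                    gy += SOBEL_X[dj + 1][di + 1] * v
            out[i, j] = finish(math.sqrt(gx * gx + gy * gy), eight_bit)
    return out


def disk(radius: int) -> list[tuple[int, int]]:
    return [
        (di, dj)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
        if di * di + dj * dj <= radius * radius
    ]


def brute_variance(a: np.ndarray, radius: int, eight_bit=True) -> np.ndarray:
    offs = disk(radius)
    out = np.zeros_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            vals = [_clamped(a, i + di, j + dj) for di, dj in offs]
            m = sum(vals) / len(vals)
            var = sum((v - m) ** 2 for v in vals) / len(vals)
            out[i, j] = finish(var, eight_bit)
    return out


def brute_median(a: np.ndarray, radius: int, eight_bit=True) -> np.ndarray:
    offs = disk(radius)
    out = np.zeros_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            vals = sorted(_clamped(a, i + di, j + dj) for di, dj in offs)
            n = len(vals)
            if n % 2 == 1:
                med = vals[n // 2]
            else:
                med = 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            out[i, j] = finish(med, eight_bit)
    return out


def brute_components_8(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by flood fill."""
    seen: set[tuple[int, int]] = set()
    comps = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj] or (si, sj) in seen:
                continue
            stack = [(si, sj)]
            comp = set()
            while stack:
                i, j = stack.pop()
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                comp.add((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (
                            0 <= ni < h
                            and 0 <= nj < w
                            and mask[ni, nj]
                            and (ni, nj) not in seen
                        ):
                            stack.append((ni, nj))
            comps.append(comp)
    return comps
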