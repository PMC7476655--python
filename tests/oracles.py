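"""Independent brute-force reference implementations.

Deliberately naive: full sorts, explicit per-pixel neighborhood loops,
and direct 3×3 convolution. These never call into the package's metric
code paths and are the ground truth for small-image equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_contrast(pixels: np.ndarray, tail_fraction: float = 0.005):
    """Full-sort tail means: (contrast_pct, i_max, i_min)."""
    flat = sorted(int(v) for v in pixels.ravel())
    t = math.ceil(tail_fraction * len(flat))
    i_min = float(np.mean(np.array(flat[:t], dtype=float)))
    i_max = float(np.mean(np.array(flat[-t:], dtype=float)))
    return (i_max - i_min) / 2**16 * 100.0, i_max, i_min


def _bin(value: int, bins: int) -> int:
    return (value * bins) // 2**16


def oracle_global_entropy(pixels: np.ndarray, bins: int = 256) -> float:
    """Histogram entropy in bits over equal-width bins, divided by log2(bins)."""
    counts = [0] * bins
    for v in pixels.ravel():
        counts[_bin(int(v), bins)] += 1
    n = pixels.size
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h / math.log2(bins)


def oracle_local_entropy_map(
    pixels: np.ndarray, window: int = 9, bins: int = 256
) -> np.ndarray:
    """Per-pixel neighborhood entropy with symmetric padding, bin-ascending sum."""
    binned = np.array(
        [[_bin(int(v), bins) for v in row] for row in pixels], dtype=np.int64
    )
    half = window // 2
    padded = np.pad(binned, half, mode="symmetric")
    h, w = binned.shape
    area = window * window
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + window, c : c + window].ravel()
            counts = np.bincount(win, minlength=bins)
            ent = 0.0
            for cnt in counts:
                if cnt > 0:
                    p = cnt / area
                    ent += -p * math.log2(p)
            out[r, c] = ent
    return out


def oracle_textured_count(
    pixels: np.ndarray, window: int = 9, bins: int = 256, cutoff: float = 3.0
) -> int:
    ent = oracle_local_entropy_map(pixels, window, bins)
    return int((ent > cutoff).sum())


def oracle_range_map(pixels: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-pixel sliding max−min with replicate padding."""
    half = window // 2
    padded = np.pad(pixels.astype(np.int64), half, mode="edge")
    h, w = pixels.shape
    out = np.zeros((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            win = padded[r : r + window, c : c + window]
            out[r, c] = int(win.max()) - int(win.min())
    return out


def oracle_highfreq_count(pixels: np.ndarray, window: int = 3, threshold: int = 6554) -> int:
    return int((oracle_range_map(pixels, window) > threshold).sum())


_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_KY = _KX.T


def oracle_edge_magnitude(pixels: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude via explicit 3×3 convolution, symmetric padding."""
    padded = np.pad(pixels.astype(np.float64), 1, mode="symmetric")
    h, w = pixels.shape
    mag = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 3, c : c + 3]
            gx = float((win * _KX).sum())
            gy = float((win * _KY).sum())
            mag[r, c] = math.sqrt(gx * gx + gy * gy)
    return mag


def oracle_edge_count(pixels: np.ndarray, scale: float = 4.0) -> int:
    mag = oracle_edge_magnitude(pixels)
    threshold = scale * float(np.mean(mag))
    return int((mag > threshold).sum())
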