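"""Per-image scene metrics.

Five quantities per luminance image: tonal-range contrast from the
brightest/darkest pixel tails, normalized global histogram entropy,
textured-area fraction from a local-entropy filter, high-spatial-frequency
area fraction from a local range filter, and edge-area fraction from a
Sobel detector with an automatic threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from visdemand.images import FULL_SCALE, LinearGrayImage, prepare_luminance

TONAL_LEVELS = FULL_SCALE + 1  # 2^16

#: High-frequency threshold: 10% of the full 16-bit tonal range.
DEFAULT_RANGE_THRESHOLD = round(0.1 * TONAL_LEVELS)


class DimensionError(ValueError):
    """Image smaller than the filter window."""


@dataclass
class MetricConfig:
    """Tunable constants of the metric suite.

    Defaults mirror the reference analysis: 0.5% tails for contrast,
    256-bin entropy histograms, a 9×9 local-entropy window with a 3-bit
    texture cutoff, a 3×3 range window thresholded at 10% of the 16-bit
    range, and Sobel edge detection with an automatic threshold.
    """

    tail_fraction: float = 0.005
    entropy_bins: int = 256
    local_window: int = 9
    entropy_cutoff_bits: float = 3.0
    range_window: int = 3
    range_threshold: int = DEFAULT_RANGE_THRESHOLD
    edge_method: str = "sobel_auto"
    #: Sobel auto threshold = edge_scale × mean gradient magnitude.
    edge_scale: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError(f"tail_fraction must be in (0, 0.5): {self.tail_fraction}")
        if self.entropy_bins < 2:
            raise ValueError(f"entropy_bins must be ≥ 2: {self.entropy_bins}")
        for name in ("local_window", "range_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and ≥ 3: {w}")
        if not 0 < self.range_threshold < TONAL_LEVELS:
            raise ValueError(
                f"range_threshold must be in (0, {TONAL_LEVELS}): {self.range_threshold}"
            )
        if self.edge_method != "sobel_auto":
            raise ValueError(f"unknown edge_method: {self.edge_method!r}")
        if self.edge_scale <= 0:
            raise ValueError(f"edge_scale must be positive: {self.edge_scale}")

    @classmethod
    def from_file(cls, path: str) -> "MetricConfig":
        with open(path) as fh:
            if str(path).endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetricIntermediates:
    """Raw counts and tail means behind :class:`SceneMetrics`."""

    i_max: float
    i_min: float
    pix_texture: int
    pix_highfreq: int
    pix_edge: int
    pix_all: int


@dataclass
class SceneMetrics:
    """The five per-image quantities, on their reporting scales."""

    contrast_pct: float
    global_entropy: float
    textured_area_pct: float
    highfreq_area_pct: float
    edge_area_pct: float

    FIELDS = (
        "contrast_pct",
        "global_entropy",
        "textured_area_pct",
        "highfreq_area_pct",
        "edge_area_pct",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


def _pixels(img: LinearGrayImage) -> np.ndarray:
    px = img.pixels
    if px.size == 0:
        raise ValueError("empty image")
    return px


def _require_window(img: LinearGrayImage, window: int, what: str) -> None:
    if img.height_px < window or img.width_px < window:
        raise DimensionError(
            f"image {img.height_px}×{img.width_px} smaller than the "
            f"{window}×{window} {what} window"
        )


def compute_contrast(
    img: LinearGrayImage, cfg: MetricConfig | None = None
) -> tuple[float, float, float]:
    """Tonal-range contrast from the pixel tails.

    Sorts all pixels, averages the ``ceil(tail_fraction·N)`` brightest
    (``i_max``) and darkest (``i_min``), and reports
    ``(i_max − i_min) / 2^16 × 100``. Division by 2^16 caps the attainable
    contrast at 65535/65536 × 100, not 100.

    Returns ``(contrast_pct, i_max, i_min)``.
    """
    cfg = cfg or MetricConfig()
    flat = np.sort(_pixels(img), axis=None)
    tail = math.ceil(cfg.tail_fraction * flat.size)
    i_min = float(np.mean(flat[:tail]))
    i_max = float(np.mean(flat[-tail:]))
    contrast = (i_max - i_min) / TONAL_LEVELS * 100.0
    return contrast, i_max, i_min


def _bin_indices(px: np.ndarray, bins: int) -> np.ndarray:
    # equal-width bins over the full 16-bit range
    return (px.astype(np.int64) * bins) // TONAL_LEVELS


def compute_global_entropy(img: LinearGrayImage, cfg: MetricConfig | None = None) -> float:
    """Normalized Shannon entropy of the tonal histogram.

    Pixels are binned into ``entropy_bins`` equal-width bins over the
    16-bit range; the entropy in bits is divided by ``log2(entropy_bins)``
    so a constant image scores 0 and a bin-uniform image scores 1.
    """
    cfg = cfg or MetricConfig()
    px = _pixels(img)
    counts = np.bincount(_bin_indices(px, cfg.entropy_bins).ravel(), minlength=cfg.entropy_bins)
    p = counts[counts > 0] / px.size
    entropy_bits = float(-np.sum(p * np.log2(p)))
    return entropy_bits / math.log2(cfg.entropy_bins)


def local_entropy_map(img: LinearGrayImage, cfg: MetricConfig | None = None) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the binned local neighborhood.

    Uses a ``local_window``² neighborhood with symmetric boundary padding
    and the same equal-width binning as the global entropy.
    """
    cfg = cfg or MetricConfig()
    _require_window(img, cfg.local_window, "local-entropy")
    binned = _bin_indices(_pixels(img), cfg.entropy_bins)
    area = cfg.local_window * cfg.local_window
    ent = np.zeros(binned.shape, dtype=np.float64)
    # one separable box filter per occupied bin; counts are exact after rounding
    for b in np.unique(binned):
        ind = (binned == b).astype(np.float64)
        counts = np.rint(
            ndimage.uniform_filter(ind, size=cfg.local_window, mode="reflect") * area
        )
        p = counts / area
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        ent += term
    return ent


def compute_textured_area(
    img: LinearGrayImage, cfg: MetricConfig | None = None
) -> tuple[float, int, int]:
    """Fraction of pixels whose local entropy exceeds the texture cutoff.

    Returns ``(textured_area_pct, pix_texture, pix_all)``.
    """
    cfg = cfg or MetricConfig()
    ent = local_entropy_map(img, cfg)
    pix_all = ent.size
    pix_texture = int(np.count_nonzero(ent > cfg.entropy_cutoff_bits))
    return 100.0 * pix_texture / pix_all, pix_texture, pix_all


def local_range_map(img: LinearGrayImage, cfg: MetricConfig | None = None) -> np.ndarray:
    """Per-pixel tonal range (max − min) of the local neighborhood.

    Uses a ``range_window``² neighborhood with replicate boundary padding.
    """
    cfg = cfg or MetricConfig()
    _require_window(img, cfg.range_window, "range")
    px = _pixels(img).astype(np.int32)
    mx = ndimage.maximum_filter(px, size=cfg.range_window, mode="nearest")
    mn = ndimage.minimum_filter(px, size=cfg.range_window, mode="nearest")
    return mx - mn


def compute_highfreq_area(
    img: LinearGrayImage, cfg: MetricConfig | None = None
) -> tuple[float, int, int]:
    """Fraction of pixels whose local range exceeds ``range_threshold``.

    Returns ``(highfreq_area_pct, pix_highfreq, pix_all)``.
    """
    cfg = cfg or MetricConfig()
    rng = local_range_map(img, cfg)
    pix_all = rng.size
    pix_highfreq = int(np.count_nonzero(rng > cfg.range_threshold))
    return 100.0 * pix_highfreq / pix_all, pix_highfreq, pix_all


def edge_map(img: LinearGrayImage, cfg: MetricConfig | None = None) -> np.ndarray:
    """Binary edge map: Sobel gradient magnitude above an automatic threshold.

    The threshold is ``edge_scale × mean(magnitude)`` (zero-gradient images
    produce an empty map). Boundary handling is symmetric padding.
    """
    cfg = cfg or MetricConfig()
    _require_window(img, 3, "Sobel")
    f = _pixels(img).astype(np.float64)
    gx = ndimage.sobel(f, axis=1, mode="reflect")
    gy = ndimage.sobel(f, axis=0, mode="reflect")
    mag = np.sqrt(gx * gx + gy * gy)
    threshold = cfg.edge_scale * float(np.mean(mag))
    return mag > threshold


def compute_edge_area(
    img: LinearGrayImage, cfg: MetricConfig | None = None
) -> tuple[float, int, int]:
    """Fraction of pixels flagged by the edge detector.

    Returns ``(edge_area_pct, pix_edge, pix_all)``.
    """
    cfg = cfg or MetricConfig()
    edges = edge_map(img, cfg)
    pix_all = edges.size
    pix_edge = int(np.count_nonzero(edges))
    return 100.0 * pix_edge / pix_all, pix_edge, pix_all


def compute_scene_metrics(
    img: LinearGrayImage, cfg: MetricConfig | None = None
) -> tuple[SceneMetrics, MetricIntermediates]:
    """Run all five metrics on one image, sharing the pixel count."""
    cfg = cfg or MetricConfig()
    contrast, i_max, i_min = compute_contrast(img, cfg)
    entropy = compute_global_entropy(img, cfg)
    textured_pct, pix_texture, pix_all = compute_textured_area(img, cfg)
    highfreq_pct, pix_highfreq, _ = compute_highfreq_area(img, cfg)
    edge_pct, pix_edge, _ = compute_edge_area(img, cfg)
    metrics = SceneMetrics(
        contrast_pct=contrast,
        global_entropy=entropy,
        textured_area_pct=textured_pct,
        highfreq_area_pct=highfreq_pct,
        edge_area_pct=edge_pct,
    )
    inter = MetricIntermediates(
        i_max=i_max,
        i_min=i_min,
        pix_texture=pix_texture,
        pix_highfreq=pix_highfreq,
        pix_edge=pix_edge,
        pix_all=pix_all,
    )
    return metrics, inter


def metrics_table(
    paths: Sequence[str], cfg: MetricConfig | None = None
) -> pd.DataFrame:
    """Batch mode: one CSV-ready row per image file.

    Each file is decoded, linearized, converted to luminance, and measured;
    columns are the filename, the five metrics, and the six intermediates.
    """
    cfg = cfg or MetricConfig()
    rows = []
    for path in paths:
        img = prepare_luminance(path)
        m, inter = compute_scene_metrics(img, cfg)
        rows.append({"filename": str(path), **m.as_dict(), **asdict(inter)})
    columns = [
        "filename",
        *SceneMetrics.FIELDS,
        "i_max",
        "i_min",
        "pix_texture",
        "pix_highfreq",
        "pix_edge",
        "pix_all",
    ]
    return pd.DataFrame(rows, columns=columns)
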