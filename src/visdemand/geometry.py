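"""Object angular size estimation and logMAR conversion.

Annotated pixel spans are mapped linearly to degrees of visual angle
through the camera's field of view (frames are assumed undistorted), and
angles are expressed as logMAR, the base-10 log of the angle in
arcminutes. The logMAR here refers to the whole object (or whole letter)
span — no letter-detail factor is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ARCMIN_PER_DEGREE = 60.0
REPORT_DECIMALS = 2


@dataclass
class CameraModel:
    """Recording-camera geometry.

    ``vfov_deg`` defaults to the horizontal field of view scaled by the
    frame aspect ratio (67.5° for the default 1920×1080 / 120° camera).
    """

    width_px: int = 1920
    height_px: int = 1080
    hfov_deg: float = 120.0
    vfov_deg: float | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if not 0 < self.hfov_deg <= 180:
            raise ValueError(f"hfov_deg must be in (0, 180]: {self.hfov_deg}")
        if self.vfov_deg is None:
            self.vfov_deg = self.hfov_deg * self.height_px / self.width_px
        if not 0 < self.vfov_deg <= 180:
            raise ValueError(f"vfov_deg must be in (0, 180]: {self.vfov_deg}")


@dataclass
class ObjectAnnotation:
    """Pixel span of one object of interest within a snapshot.

    When ``is_text`` is set the spans describe a single letter rather than
    the whole text block.
    """

    snapshot_id: str
    span_h_px: int
    span_v_px: int
    is_text: bool = False

    def __post_init__(self) -> None:
        if self.span_h_px < 1 or self.span_v_px < 1:
            raise ValueError(
                f"pixel spans must be ≥ 1, got ({self.span_h_px}, {self.span_v_px})"
            )


@dataclass
class AngularSize:
    """Angular extent of one object, in degrees and logMAR, per axis."""

    deg_h: float
    deg_v: float
    logmar_h: float
    logmar_v: float


def pixel_span_to_degrees(span_px: int, axis: str, cam: CameraModel) -> float:
    """Linear angular mapping of a pixel span through the field of view."""
    if axis == "h":
        dim, fov = cam.width_px, cam.hfov_deg
    elif axis == "v":
        dim, fov = cam.height_px, cam.vfov_deg
    else:
        raise ValueError(f"axis must be 'h' or 'v', got {axis!r}")
    if not 1 <= span_px <= dim:
        raise ValueError(f"span {span_px} px outside frame dimension {dim} px")
    return span_px / dim * fov


def degrees_to_logmar(deg: float) -> float:
    """logMAR of an angular size: log10 of the angle in arcminutes."""
    if deg <= 0:
        raise ValueError(f"angular size must be positive, got {deg}")
    return math.log10(deg * ARCMIN_PER_DEGREE)


def logmar_to_degrees(logmar: float) -> float:
    """Inverse of :func:`degrees_to_logmar`."""
    return 10.0**logmar / ARCMIN_PER_DEGREE


def annotate_size(ann: ObjectAnnotation, cam: CameraModel) -> AngularSize:
    """Degrees and logMAR for both axes of one annotation."""
    deg_h = pixel_span_to_degrees(ann.span_h_px, "h", cam)
    deg_v = pixel_span_to_degrees(ann.span_v_px, "v", cam)
    return AngularSize(
        deg_h=deg_h,
        deg_v=deg_v,
        logmar_h=degrees_to_logmar(deg_h),
        logmar_v=degrees_to_logmar(deg_v),
    )


@dataclass
class AxisSummary:
    """Distribution summary of angular sizes along one axis.

    The logMAR entries are conversions of the degree *statistics* (mean,
    SD, min, max), not statistics of per-object logMAR values. ``sd_logmar``
    is NaN when the degree SD is 0.
    """

    mean_deg: float
    sd_deg: float
    min_deg: float
    max_deg: float
    mean_logmar: float
    sd_logmar: float
    min_logmar: float
    max_logmar: float
    frac_below_threshold: float


@dataclass
class SizeSummary:
    horizontal: AxisSummary
    vertical: AxisSummary
    threshold_deg: float
    n: int


def _axis_summary(degs: np.ndarray, threshold_deg: float) -> AxisSummary:
    mean = float(np.mean(degs))
    sd = float(np.std(degs, ddof=1)) if degs.size > 1 else 0.0
    lo = float(np.min(degs))
    hi = float(np.max(degs))
    return AxisSummary(
        mean_deg=mean,
        sd_deg=sd,
        min_deg=lo,
        max_deg=hi,
        mean_logmar=degrees_to_logmar(mean),
        sd_logmar=degrees_to_logmar(sd) if sd > 0 else float("nan"),
        min_logmar=degrees_to_logmar(lo),
        max_logmar=degrees_to_logmar(hi),
        frac_below_threshold=float(np.mean(degs < threshold_deg)),
    )


def summarize_object_sizes(
    sizes: Sequence[AngularSize], threshold_deg: float = 2.0
) -> SizeSummary:
    """Per-axis mean/SD/min/max in degrees plus logMAR equivalents.

    ``frac_below_threshold`` is the fraction of objects strictly below
    ``threshold_deg``. A single-object input yields SD 0 and a
    degenerate-sample warning.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size list")
    if len(sizes) == 1:
        warnings.warn(
            "size summary over a single object: SD reported as 0",
            stacklevel=2,
        )
    deg_h = np.array([s.deg_h for s in sizes])
    deg_v = np.array([s.deg_v for s in sizes])
    return SizeSummary(
        horizontal=_axis_summary(deg_h, threshold_deg),
        vertical=_axis_summary(deg_v, threshold_deg),
        threshold_deg=threshold_deg,
        n=len(sizes),
    )


def round_logmar(value: float) -> float:
    """Reporting convention: logMAR printed to 2 decimals."""
    return round(value, REPORT_DECIMALS)


def read_annotations(path: str) -> list[ObjectAnnotation]:
    """Load annotations from CSV (snapshot_id, span_h_px, span_v_px[, is_text])."""
    df = pd.read_csv(path)
    required = {"snapshot_id", "span_h_px", "span_v_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    anns = []
    for row in df.itertuples(index=False):
        anns.append(
            ObjectAnnotation(
                snapshot_id=str(row.snapshot_id),
                span_h_px=int(row.span_h_px),
                span_v_px=int(row.span_v_px),
                is_text=bool(getattr(row, "is_text", False)),
            )
        )
    return anns


def annotations_to_sizes(
    anns: Iterable[ObjectAnnotation], cam: CameraModel
) -> list[AngularSize]:
    return [annotate_size(a, cam) for a in anns]
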