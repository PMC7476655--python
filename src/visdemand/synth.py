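"""Synthetic fixtures with analytically known ground truth.

Because the study recordings are not public, every pipeline stage is
exercised on generated data: images whose metric values are known by
construction (constant, checkerboard, noise, ramp, tail-controlled),
object scenes with exact pixel spans, and coding tables with planted
task probabilities, category probabilities, and dual-coder agreement.

All randomness goes through ``numpy.random.default_rng`` (PCG64) so a
fixed seed reproduces bit-identical fixtures across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from visdemand.coding import (
    ClassifierSpec,
    SceneCode,
    TaskRecord,
    default_schema,
    map_task,
)
from visdemand.geometry import CameraModel, ObjectAnnotation
from visdemand.images import FULL_SCALE, LinearGrayImage
from visdemand.metrics import TONAL_LEVELS


@dataclass
class ImageFixture:
    """A generated image plus the metric values it is built to produce.

    ``expected`` maps metric names to ``{"value": v, "tol": t}``; only
    analytically known entries are present. Tolerances travel with the
    fixture, not with test code.
    """

    image: LinearGrayImage
    expected: dict[str, dict[str, float]]
    recipe: str
    seed: int | None = None
    notes: str = ""


@dataclass
class CodingFixture:
    """Generated coding tables plus the ground truth planted in them."""

    task_records: list[TaskRecord] = field(default_factory=list)
    scene_codes: list[SceneCode] = field(default_factory=list)
    coder_a: list[SceneCode] = field(default_factory=list)
    coder_b: list[SceneCode] = field(default_factory=list)
    planted: dict = field(default_factory=dict)
    seed: int | None = None


def _check_value(value: int) -> int:
    if not 0 <= value <= FULL_SCALE:
        raise ValueError(f"pixel value {value} outside [0, {FULL_SCALE}]")
    return int(value)


def gen_constant(h: int, w: int, value: int) -> ImageFixture:
    """Uniform image: every metric is exactly zero.

    Frames smaller than the 9×9 local-entropy window are flagged as usable
    only for window-free operations.
    """
    value = _check_value(value)
    img = LinearGrayImage(np.full((h, w), value, dtype=np.uint16))
    expected = {
        "contrast_pct": {"value": 0.0, "tol": 0.0},
        "global_entropy": {"value": 0.0, "tol": 0.0},
    }
    notes = ""
    if h >= 9 and w >= 9:
        expected["textured_area_pct"] = {"value": 0.0, "tol": 0.0}
    if h >= 3 and w >= 3:
        expected["highfreq_area_pct"] = {"value": 0.0, "tol": 0.0}
        expected["edge_area_pct"] = {"value": 0.0, "tol": 0.0}
    if h < 9 or w < 9:
        notes = "smaller than the 9×9 entropy window; windowed metrics omitted"
    return ImageFixture(image=img, expected=expected, recipe=f"constant({h},{w},{value})", notes=notes)


def gen_checkerboard(h: int, w: int, pitch_px: int, lo: int, hi: int) -> ImageFixture:
    """Two-tone checkerboard with square cells of ``pitch_px``.

    At pitch 1 with full-range tones every 3×3 neighborhood spans the full
    tonal range, so the high-frequency area is exactly 100%.
    """
    lo, hi = _check_value(lo), _check_value(hi)
    if pitch_px < 1:
        raise ValueError("pitch_px must be ≥ 1")
    r, c = np.indices((h, w))
    board = ((r // pitch_px + c // pitch_px) % 2).astype(np.uint16)
    img = LinearGrayImage(np.where(board == 1, np.uint16(hi), np.uint16(lo)))
    expected: dict[str, dict[str, float]] = {}
    if lo != hi:
        # tails are far smaller than either tone's population
        expected["contrast_pct"] = {
            "value": (hi - lo) / TONAL_LEVELS * 100.0,
            "tol": 1e-9,
        }
        if pitch_px == 1 and hi - lo > 6554 and h >= 3 and w >= 3:
            expected["highfreq_area_pct"] = {"value": 100.0, "tol": 0.0}
    return ImageFixture(
        image=img,
        expected=expected,
        recipe=f"checkerboard({h},{w},{pitch_px},{lo},{hi})",
    )


def gen_noise(h: int, w: int, seed: int) -> ImageFixture:
    """I.i.d. uniform noise over the full 16-bit range.

    For 256×256 and larger, the global entropy is ≈ 1 and essentially the
    whole image counts as textured (each 9×9 window holds 81 nearly
    distinct tones, entropy ≈ log2 81 ≈ 6.3 bits ≫ 3).
    """
    rng = np.random.default_rng(seed)
    px = rng.integers(0, TONAL_LEVELS, size=(h, w), dtype=np.uint16)
    img = LinearGrayImage(px)
    expected: dict[str, dict[str, float]] = {}
    if h * w >= 256 * 256:
        expected["global_entropy"] = {"value": 1.0, "tol": 0.01}
        expected["textured_area_pct"] = {"value": 100.0, "tol": 0.5}
    return ImageFixture(image=img, expected=expected, recipe=f"noise({h},{w})", seed=seed)


def gen_half_noise(h: int, w: int, seed: int) -> ImageFixture:
    """Left half constant mid-gray, right half full-range noise.

    The textured area is ≈ 50% with a tolerance covering the boundary band
    where entropy windows straddle the seam (±4 columns for the 9×9
    window).
    """
    rng = np.random.default_rng(seed)
    px = np.full((h, w), 32768, dtype=np.uint16)
    half = w // 2
    px[:, half:] = rng.integers(0, TONAL_LEVELS, size=(h, w - half), dtype=np.uint16)
    img = LinearGrayImage(px)
    expected: dict[str, dict[str, float]] = {}
    if h >= 64 and w >= 64:
        expected["textured_area_pct"] = {"value": 100.0 * (w - half) / w, "tol": 4.0}
    return ImageFixture(image=img, expected=expected, recipe=f"half_noise({h},{w})", seed=seed)


def gen_ramp(h: int, w: int, step: int) -> ImageFixture:
    """Horizontal luminance ramp increasing ``step`` counts per column.

    Every 3×3 window spans at most ``2·step`` counts, so for small steps
    the high-frequency area is exactly zero.
    """
    if step < 0 or (w - 1) * step > FULL_SCALE:
        raise ValueError(f"ramp exceeds the 16-bit range: step {step}, width {w}")
    px = np.tile(np.arange(w, dtype=np.uint16) * step, (h, 1))
    img = LinearGrayImage(px)
    expected: dict[str, dict[str, float]] = {}
    if h >= 3 and w >= 3 and 2 * step <= 6554:
        expected["highfreq_area_pct"] = {"value": 0.0, "tol": 0.0}
    return ImageFixture(image=img, expected=expected, recipe=f"ramp({h},{w},{step})")


def _tail_values(mean: float, tail: int) -> tuple[np.ndarray, float]:
    # integer pixels whose average is as close to `mean` as t pixels allow:
    # k of them at floor(mean)+1, the rest at floor(mean)
    base = math.floor(mean)
    k = round((mean - base) * tail)
    if base < 0 or base + (1 if k else 0) > FULL_SCALE:
        raise ValueError(f"tail mean {mean} outside the 16-bit range")
    values = np.full(tail, base, dtype=np.int64)
    values[:k] += 1
    achieved = (base * tail + k) / tail
    return values, achieved


def gen_tail_controlled(
    h: int, w: int, top_mean: float, bottom_mean: float, tail_fraction: float = 0.005
) -> ImageFixture:
    """Image whose brightest/darkest tails have the requested means.

    Exactly ``ceil(tail_fraction·N)`` pixels form each tail, with the
    remainder strictly between, so the contrast is
    ``(top_mean − bottom_mean)/2^16 × 100`` by construction. Fractional
    means are realized as a mix of two adjacent integer levels (exact
    whenever ``mean × tail_count`` is an integer); the achieved means are
    what the expected contrast is computed from.
    """
    if top_mean - bottom_mean < 4:
        raise ValueError("top_mean must exceed bottom_mean by at least 4")
    n = h * w
    tail = math.ceil(tail_fraction * n)
    if 2 * tail >= n:
        raise ValueError(f"image too small for two {tail}-pixel tails")
    bottom_vals, bottom_ach = _tail_values(bottom_mean, tail)
    top_vals, top_ach = _tail_values(top_mean, tail)
    mid = int((math.floor(top_mean) + math.ceil(bottom_mean)) // 2)
    if not bottom_vals.max() < mid < top_vals.min():
        raise ValueError("tail means too close to fit interior pixels between them")
    flat = np.full(n, mid, dtype=np.int64)
    flat[:tail] = bottom_vals
    flat[-tail:] = top_vals
    img = LinearGrayImage(flat.reshape(h, w).astype(np.uint16))
    contrast = (top_ach - bottom_ach) / TONAL_LEVELS * 100.0
    return ImageFixture(
        image=img,
        expected={"contrast_pct": {"value": contrast, "tol": 1e-9}},
        recipe=f"tail_controlled({h},{w},{top_mean},{bottom_mean})",
    )


def gen_object_scene(
    cam: CameraModel, span_h_px: int, span_v_px: int
) -> tuple[ImageFixture, ObjectAnnotation]:
    """Frame with a centered high-contrast rectangle of exact pixel span."""
    if span_h_px < 1 or span_v_px < 1:
        raise ValueError(f"spans must be ≥ 1, got ({span_h_px}, {span_v_px})")
    if span_h_px > cam.width_px or span_v_px > cam.height_px:
        raise ValueError("object span exceeds the frame")
    px = np.zeros((cam.height_px, cam.width_px), dtype=np.uint16)
    r0 = (cam.height_px - span_v_px) // 2
    c0 = (cam.width_px - span_h_px) // 2
    px[r0 : r0 + span_v_px, c0 : c0 + span_h_px] = FULL_SCALE
    fixture = ImageFixture(
        image=LinearGrayImage(px),
        expected={},
        recipe=f"object_scene({span_h_px},{span_v_px})",
    )
    ann = ObjectAnnotation(
        snapshot_id=f"object_{span_h_px}x{span_v_px}",
        span_h_px=span_h_px,
        span_v_px=span_v_px,
    )
    return fixture, ann


def _draw(probs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = sorted(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    return labels, p


def gen_coding_dataset(
    n_participants: int,
    n_records: int,
    task_probs: Mapping[str, float],
    classifier_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    schema: Sequence[ClassifierSpec] | None = None,
) -> CodingFixture:
    """Task records and scene codes with planted multinomial ground truth.

    Tasks are drawn from ``task_probs``; each record is assigned a
    participant uniformly. Scene-code categories follow
    ``classifier_probs`` where given and are uniform over the schema
    categories otherwise.
    """
    if n_participants < 1 or n_records < 1:
        raise ValueError("need at least one participant and one record")
    schema = list(schema) if schema is not None else default_schema()
    classifier_probs = dict(classifier_probs or {})
    rng = np.random.default_rng(seed)

    labels, p = _draw(task_probs)
    tasks = rng.choice(labels, size=n_records, p=p)
    participants = rng.integers(0, n_participants, size=n_records)

    records: list[TaskRecord] = []
    codes: list[SceneCode] = []
    for i in range(n_records):
        snapshot_id = f"s{i:05d}"
        label, bespoke = map_task(str(tasks[i]))
        records.append(
            TaskRecord(
                participant_id=f"p{participants[i]:03d}",
                snapshot_id=snapshot_id,
                narrative=str(tasks[i]).casefold(),
                task_label=label,
                is_bespoke=bespoke,
            )
        )
        values = {}
        for spec in schema:
            if spec.name in classifier_probs:
                cats, cp = _draw(classifier_probs[spec.name])
                values[spec.name] = str(rng.choice(cats, p=cp))
            else:
                values[spec.name] = str(rng.choice(list(spec.categories)))
        codes.append(SceneCode(snapshot_id=snapshot_id, values=values))

    return CodingFixture(
        task_records=records,
        scene_codes=codes,
        planted={
            "task_probs": dict(task_probs),
            "classifier_probs": {k: dict(v) for k, v in classifier_probs.items()},
            "n_participants": n_participants,
        },
        seed=seed,
    )


def gen_dual_coder(
    n_items: int, agreement_rate: float, k_categories: int, seed: int = 0
) -> CodingFixture:
    """Paired coder tables with a planted agreement rate.

    Coder A draws uniformly among ``k_categories``; with probability
    ``agreement_rate`` coder B copies A, otherwise B draws uniformly among
    the other k−1 categories. Disagreement draws can never collide with A,
    so the expected raw agreement equals ``agreement_rate`` exactly; the
    planted expectation is stored with the fixture.
    """
    if not 0.0 <= agreement_rate <= 1.0:
        raise ValueError(f"agreement_rate must be in [0, 1]: {agreement_rate}")
    if k_categories < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    cats = [f"c{j}" for j in range(k_categories)]
    a_idx = rng.integers(0, k_categories, size=n_items)
    copy = rng.random(n_items) < agreement_rate
    # uniform among the other k−1: draw offset 1..k−1 and rotate
    offsets = rng.integers(1, k_categories, size=n_items)
    b_idx = np.where(copy, a_idx, (a_idx + offsets) % k_categories)

    coder_a = [
        SceneCode(snapshot_id=f"s{i:05d}", values={"planted": cats[a_idx[i]]})
        for i in range(n_items)
    ]
    coder_b = [
        SceneCode(snapshot_id=f"s{i:05d}", values={"planted": cats[b_idx[i]]})
        for i in range(n_items)
    ]
    return CodingFixture(
        coder_a=coder_a,
        coder_b=coder_b,
        planted={
            "agreement_rate": agreement_rate,
            "expected_agreement_pct": 100.0 * agreement_rate,
            "k_categories": k_categories,
        },
        seed=seed,
    )
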