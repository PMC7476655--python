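from __future__ import annotations

import numpy as np
import pytest

from visdemand.images import LinearGrayImage
from visdemand.metrics import MetricConfig


@pytest.fixture(scope="session")
def cfg() -> MetricConfig:
    return MetricConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200902)


def random_small_image(rng: np.random.Generator, max_side: int = 32) -> LinearGrayImage:
    """A random image no larger than max_side², at least 9×9 so every metric applies."""
    h = int(rng.integers(9, max_side + 1))
    w = int(rng.integers(9, max_side + 1))
    kind = rng.integers(0, 3)
    if kind == 0:  # full-range noise
        px = rng.integers(0, 65536, size=(h, w))
    elif kind == 1:  # low-dynamic-range noise: exercises binning edges
        lo = int(rng.integers(0, 60000))
        px = rng.integers(lo, lo + int(rng.integers(2, 5000)), size=(h, w))
    else:  # piecewise-constant blocks: exercises ties and plateaus
        px = np.repeat(
            np.repeat(rng.integers(0, 65536, size=(3, 3)), h // 3 + 1, axis=0),
            w // 3 + 1,
            axis=1,
        )[:h, :w]
    return LinearGrayImage(np.clip(px, 0, 65535).astype(np.uint16))
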