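from __future__ import annotations

import numpy as np
import pytest

import oracles
from visdemand.images import LinearGrayImage
from visdemand.metrics import (
    DEFAULT_RANGE_THRESHOLD,
    DimensionError,
    MetricConfig,
    compute_contrast,
    compute_edge_area,
    compute_global_entropy,
    compute_highfreq_area,
    compute_scene_metrics,
    compute_textured_area,
)
from visdemand.synth import gen_checkerboard, gen_constant, gen_noise, gen_ramp, gen_tail_controlled


def _img(px):
    return LinearGrayImage(np.asarray(px, dtype=np.uint16))


def _constant(value, shape=(16, 16)):
    return _img(np.full(shape, value))


class TestConfig:
    def test_default_threshold_is_ten_percent_of_range(self):
        assert DEFAULT_RANGE_THRESHOLD == round(0.1 * 2**16) == 6554
        assert MetricConfig().range_threshold == 6554

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tail_fraction": 0.0},
            {"tail_fraction": 0.5},
            {"local_window": 8},
            {"range_window": 1},
            {"range_threshold": 0},
            {"range_threshold": 65536},
            {"edge_method": "canny"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MetricConfig(**kwargs)

    def test_config_file_round_trip(self, tmp_path):
        import yaml

        cfg = MetricConfig(tail_fraction=0.01, entropy_cutoff_bits=2.5)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert MetricConfig.from_file(str(path)) == cfg


class TestContrast:
    def test_constant_image_zero(self, cfg):
        contrast, i_max, i_min = compute_contrast(_constant(32768), cfg)
        assert contrast == 0.0
        assert i_max == i_min == 32768

    def test_half_black_half_white(self, cfg):
        px = np.zeros((16, 16), dtype=np.uint16)
        px[8:] = 65535
        contrast, _, _ = compute_contrast(_img(px), cfg)
        assert contrast == pytest.approx(65535 / 65536 * 100)

    def test_tail_controlled_fixture_hits_80(self, cfg):
        # 90% and 10% of the 16-bit range as tail means → contrast 80 exactly
        fix = gen_tail_controlled(100, 100, 58982.4, 6553.6)
        contrast, _, _ = compute_contrast(fix.image, cfg)
        assert contrast == pytest.approx(80.0, abs=fix.expected["contrast_pct"]["tol"])

    def test_matches_full_sort_oracle(self, rng, cfg):
        px = rng.integers(0, 65536, size=(25, 31)).astype(np.uint16)
        got = compute_contrast(_img(px), cfg)
        want = oracles.oracle_contrast(px)
        assert got == pytest.approx(want, rel=1e-12)


class TestGlobalEntropy:
    def test_constant_zero(self, cfg):
        assert compute_global_entropy(_constant(123), cfg) == 0.0

    def test_two_equal_bins_is_one_eighth(self, cfg):
        px = np.zeros((16, 16), dtype=np.uint16)
        px[8:] = 65535  # two bins, equally frequent → 1 bit of 8
        assert compute_global_entropy(_img(px), cfg) == pytest.approx(0.125)

    def test_uniform_over_bins_is_one(self, cfg):
        # one pixel per bin value, all 256 bins equally populated
        px = (np.arange(256, dtype=np.uint16) * 256).reshape(16, 16)
        assert compute_global_entropy(_img(px), cfg) == pytest.approx(1.0)

    def test_matches_histogram_oracle(self, rng, cfg):
        px = rng.integers(0, 65536, size=(20, 20)).astype(np.uint16)
        got = compute_global_entropy(_img(px), cfg)
        assert got == pytest.approx(oracles.oracle_global_entropy(px), rel=1e-12)


class TestTexturedArea:
    def test_constant_zero(self, cfg):
        pct, count, total = compute_textured_area(_constant(999), cfg)
        assert (pct, count) == (0.0, 0)
        assert total == 256

    def test_noise_covers_nearly_everything(self, cfg):
        fix = gen_noise(256, 256, seed=7)
        pct, _, _ = compute_textured_area(fix.image, cfg)
        assert pct > 99.0

    def test_half_noise_covers_about_half(self, cfg):
        from visdemand.synth import gen_half_noise

        fix = gen_half_noise(256, 256, seed=11)
        pct, _, _ = compute_textured_area(fix.image, cfg)
        exp = fix.expected["textured_area_pct"]
        assert pct == pytest.approx(exp["value"], abs=exp["tol"])

    def test_too_small_image_rejected(self, cfg):
        with pytest.raises(DimensionError):
            compute_textured_area(_constant(0, shape=(8, 8)), cfg)

    def test_matches_neighborhood_oracle(self, rng, cfg):
        px = rng.integers(0, 65536, size=(14, 17)).astype(np.uint16)
        _, count, _ = compute_textured_area(_img(px), cfg)
        assert count == oracles.oracle_textured_count(px)


class TestHighFreqArea:
    def test_constant_zero(self, cfg):
        pct, count, _ = compute_highfreq_area(_constant(500), cfg)
        assert (pct, count) == (0.0, 0)

    def test_unit_checkerboard_full_coverage(self, cfg):
        fix = gen_checkerboard(64, 64, 1, 0, 65535)
        pct, _, _ = compute_highfreq_area(fix.image, cfg)
        assert pct == 100.0

    def test_gentle_ramp_zero(self, cfg):
        fix = gen_ramp(64, 64, 10)
        pct, _, _ = compute_highfreq_area(fix.image, cfg)
        assert pct == 0.0

    def test_matches_sliding_window_oracle(self, rng, cfg):
        px = rng.integers(0, 65536, size=(13, 19)).astype(np.uint16)
        _, count, _ = compute_highfreq_area(_img(px), cfg)
        assert count == oracles.oracle_highfreq_count(px)


class TestEdgeArea:
    def test_constant_zero(self, cfg):
        pct, count, _ = compute_edge_area(_constant(40000), cfg)
        assert (pct, count) == (0.0, 0)

    def test_vertical_step_edge_band(self, cfg):
        px = np.zeros((100, 100), dtype=np.uint16)
        px[:, 50:] = 65535
        pct, count, _ = compute_edge_area(_img(px), cfg)
        # frozen from the independent convolution oracle
        assert count == oracles.oracle_edge_count(px)
        assert 1.0 <= pct <= 2.0

    def test_checkerboard_exceeds_constant(self, cfg):
        # coarse pitch: boundary pixels are sparse enough to clear the
        # 4×mean automatic threshold
        fix = gen_checkerboard(32, 32, 16, 0, 65535)
        pct_board, _, _ = compute_edge_area(fix.image, cfg)
        pct_const, _, _ = compute_edge_area(_constant(0, shape=(32, 32)), cfg)
        assert pct_board > pct_const

    def test_matches_convolution_oracle(self, rng, cfg):
        px = rng.integers(0, 65536, size=(21, 16)).astype(np.uint16)
        _, count, _ = compute_edge_area(_img(px), cfg)
        assert count == oracles.oracle_edge_count(px)


class TestComposite:
    def test_constant_image_all_zero(self, cfg):
        fix = gen_constant(64, 64, 32768)
        metrics, inter = compute_scene_metrics(fix.image, cfg)
        assert metrics.contrast_pct == 0.0
        assert metrics.global_entropy == 0.0
        assert metrics.textured_area_pct == 0.0
        assert metrics.highfreq_area_pct == 0.0
        assert metrics.edge_area_pct == 0.0
        assert inter.pix_all == 64 * 64

    def test_deterministic_on_fixed_fixture(self, cfg):
        fix = gen_noise(64, 64, seed=3)
        first, _ = compute_scene_metrics(fix.image, cfg)
        second, _ = compute_scene_metrics(fix.image, cfg)
        assert first == second

    def test_ranges_hold_for_random_image(self, rng, cfg):
        px = rng.integers(0, 65536, size=(32, 32)).astype(np.uint16)
        metrics, inter = compute_scene_metrics(_img(px), cfg)
        assert 0 <= metrics.contrast_pct <= 100
        assert 0 <= metrics.global_entropy <= 1
        for pct in (
            metrics.textured_area_pct,
            metrics.highfreq_area_pct,
            metrics.edge_area_pct,
        ):
            assert 0 <= pct <= 100
        assert 0 <= inter.i_min <= inter.i_max <= 65535
        assert max(inter.pix_texture, inter.pix_highfreq, inter.pix_edge) <= inter.pix_all


class TestBatch:
    def test_metrics_table_shape(self, tmp_path, cfg):
        import tifffile

        from visdemand.metrics import metrics_table

        for i, value in enumerate((0, 30000, 65535)):
            tifffile.imwrite(
                tmp_path / f"im{i}.tiff", np.full((9, 9, 3), value, dtype=np.uint16)
            )
        paths = sorted(str(p) for p in tmp_path.glob("*.tiff"))
        table = metrics_table(paths, cfg)
        assert len(table) == 3
        assert list(table.columns[:6]) == [
            "filename",
            "contrast_pct",
            "global_entropy",
            "textured_area_pct",
            "highfreq_area_pct",
            "edge_area_pct",
        ]
        # constant frames: every metric zero regardless of level
        assert np.allclose(table[table.columns[1:6]].to_numpy(), 0.0)
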