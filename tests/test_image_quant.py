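"""Detection and metrics against hand-built grids, naive oracles, and the
generator's ground truth."""

import dataclasses

import numpy as np
import pytest

from mitoquant.image_quant import (
    Component,
    MitolysosomeSet,
    SegmentationConfig,
    aggregate_per_animal,
    compute_metrics,
    compute_ratio,
    denoise,
    detect_mitolysosomes,
    quantify_image,
    segment_population,
    segment_tissue,
)
from mitoquant.micrograph import Micrograph
from mitoquant.synthetic_data import SynthImageParams, generate_tissue_image
from oracles import brute_force_detect, naive_median3x3, naive_ratio

import pandas as pd


class TestDenoise:
    def test_constant_grid_unchanged(self, default_config):
        grid = np.full((20, 20), 1234.0)
        np.testing.assert_array_equal(denoise(grid, default_config), grid)

    def test_single_impulse_removed_by_median(self, default_config):
        grid = np.zeros((9, 9))
        grid[4, 4] = 60000.0
        assert denoise(grid, default_config).max() == 0.0

    def test_random_grid_matches_naive_median_oracle(self, default_config):
        rng = np.random.default_rng(21)
        grid = rng.uniform(0, 65535, size=(32, 32))
        np.testing.assert_array_equal(denoise(grid, default_config), naive_median3x3(grid))

    def test_even_median_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SegmentationConfig(fine_filter_size=4)

    def test_gaussian_and_none_kinds(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(100, 5000, size=(16, 16))
        cfg_g = SegmentationConfig(fine_filter_kind="gaussian")
        out = denoise(grid, cfg_g)
        assert out.shape == grid.shape
        assert out.min() >= grid.min() and out.max() <= grid.max()
        cfg_n = SegmentationConfig(fine_filter_kind="none")
        np.testing.assert_array_equal(denoise(grid, cfg_n), grid)


class TestSegmentTissue:
    def test_noiseless_bimodal_recovers_generator_mask(self, noiseless_scene, default_config):
        img, gt = noiseless_scene
        mask = segment_tissue(denoise(img.green, default_config), default_config)
        np.testing.assert_array_equal(mask, gt.tissue_mask)

    def test_all_zero_image_warns_and_returns_empty(self, default_config):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_tissue(np.zeros((8, 8)), default_config)
        assert not mask.any()

    def test_noisy_mask_area_close_to_truth(self, default_config):
        img, gt = generate_tissue_image(SynthImageParams(image_size_px=(256, 256), seed=9))
        mask = segment_tissue(denoise(img.green, default_config), default_config)
        assert mask.sum() == pytest.approx(gt.tissue_mask.sum(), rel=0.02)

    def test_fixed_threshold_mode(self):
        cfg = SegmentationConfig(tissue_threshold_method="fixed", tissue_threshold_value=500.0)
        grid = np.array([[100.0, 600.0], [700.0, 100.0]])
        mask = segment_tissue(grid, cfg)
        # the two bright pixels pass; no enclosed hole to fill
        assert mask.sum() == 2


class TestSegmentPopulation:
    def test_absent_label_channel_rejected(self, default_config):
        with pytest.raises(ValueError, match="label channel is absent"):
            segment_population(None, default_config)

    def test_zero_label_gives_empty_mask(self, default_config):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_population(np.zeros((8, 8)), default_config)
        assert not mask.any()

    def test_population_fraction_recovered(self, default_config):
        p = SynthImageParams(image_size_px=(256, 256), population_fraction=0.3, seed=12)
        img, gt = generate_tissue_image(p)
        cfg = default_config
        tissue = segment_tissue(denoise(img.green, cfg), cfg)
        pop = segment_population(denoise(img.label, cfg), cfg) & tissue
        frac = pop.sum() / tissue.sum()
        assert frac == pytest.approx(0.3, rel=0.03)


class TestComputeRatio:
    def test_equal_channels_no_epsilon(self):
        g = np.full((4, 4), 100.0)
        np.testing.assert_array_equal(compute_ratio(g, g, 0.0), np.ones((4, 4)))

    def test_zero_green_with_epsilon(self):
        red = np.full((2, 2), 200.0)
        green = np.zeros((2, 2))
        np.testing.assert_array_equal(compute_ratio(red, green, 1.0), np.full((2, 2), 200.0))

    def test_zero_epsilon_with_zero_green_rejected(self):
        with pytest.raises(ValueError, match="divide by zero"):
            compute_ratio(np.ones((2, 2)), np.zeros((2, 2)), 0.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(8)
        red = rng.uniform(0, 65535, (12, 12))
        green = rng.uniform(0, 65535, (12, 12))
        np.testing.assert_allclose(compute_ratio(red, green, 1.0), naive_ratio(red, green, 1.0), rtol=0, atol=0)


def _tiny_config(**kw) -> SegmentationConfig:
    base = dict(
        fine_filter_kind="none",
        tissue_threshold_method="fixed",
        tissue_threshold_value=50.0,
        ratio_epsilon=1.0,
        ratio_threshold=1.5,
        red_threshold_method="fixed",
        red_threshold_value=150.0,
        min_puncta_area_px=1,
        connectivity=8,
    )
    base.update(kw)
    return SegmentationConfig(**base)


class TestDetect:
    def test_uniform_tissue_no_puncta_detects_nothing(self):
        g = np.full((16, 16), 5000.0)
        micro = Micrograph(green=g, red=g.copy(), pixel_size_um=0.1)
        dets = detect_mitolysosomes(micro, _tiny_config())
        assert len(dets) == 0

    def test_diagonal_puncta_connectivity(self):
        # two 2-px puncta touching only diagonally
        green = np.full((10, 10), 1000.0)
        red = np.full((10, 10), 1000.0)
        for y, x in [(3, 3), (3, 4), (4, 5), (4, 6)]:
            green[y, x] = 10.0
            red[y, x] = 3000.0
        micro = Micrograph(green=green, red=red, pixel_size_um=0.1)
        assert len(detect_mitolysosomes(micro, _tiny_config(connectivity=8))) == 1
        assert len(detect_mitolysosomes(micro, _tiny_config(connectivity=4))) == 2

    def test_min_area_filter(self):
        green = np.full((10, 10), 1000.0)
        red = np.full((10, 10), 1000.0)
        green[2, 2] = 10.0
        red[2, 2] = 3000.0
        micro = Micrograph(green=green, red=red, pixel_size_um=0.1)
        assert len(detect_mitolysosomes(micro, _tiny_config(min_puncta_area_px=1))) == 1
        assert len(detect_mitolysosomes(micro, _tiny_config(min_puncta_area_px=2))) == 0

    def test_noiseless_synthetic_counts_exact(self, noiseless_scene, default_config):
        img, gt = noiseless_scene
        dets = detect_mitolysosomes(img, default_config)
        assert len(dets) == gt.merged_count

    def test_ratio_invariance_under_channel_scaling(self, noiseless_scene):
        img, _ = noiseless_scene
        c = 0.25  # scale down to stay within 16-bit range
        cfg = _tiny_config(
            tissue_threshold_value=2000.0, ratio_threshold=2.0, red_threshold_value=9000.0
        )
        cfg_scaled = dataclasses.replace(
            cfg,
            tissue_threshold_value=cfg.tissue_threshold_value * c,
            ratio_epsilon=cfg.ratio_epsilon * c,
            red_threshold_value=cfg.red_threshold_value * c,
        )
        scaled = Micrograph(
            green=np.asarray(img.green, dtype=float) * c,
            red=np.asarray(img.red, dtype=float) * c,
            pixel_size_um=img.pixel_size_um,
        )
        d1 = detect_mitolysosomes(img, cfg)
        d2 = detect_mitolysosomes(scaled, cfg_scaled)
        assert [(c1.area_px, c1.centroid_row, c1.centroid_col) for c1 in d1.components] == [
            (c2.area_px, c2.centroid_row, c2.centroid_col) for c2 in d2.components
        ]

    def test_component_count_monotone_in_ratio_threshold(self, default_config):
        img, _ = generate_tissue_image(SynthImageParams(image_size_px=(256, 256), seed=33))
        counts = []
        for thr in (1.5, 2.0, 3.0, 5.0, 10.0, 20.0):
            cfg = dataclasses.replace(default_config, ratio_threshold=thr)
            counts.append(len(detect_mitolysosomes(img, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_detected_count_increases_with_density(self):
        """Expected detections rise with ground-truth density (over seeds)."""
        def mean_count(density):
            tot = 0
            for seed in range(8):
                p = SynthImageParams(
                    image_size_px=(128, 128), puncta_density_per_mm2=density, seed=seed
                )
                img, _ = generate_tissue_image(p)
                tot += len(detect_mitolysosomes(img, SegmentationConfig()))
            return tot / 8

        assert mean_count(40000.0) > mean_count(8000.0)

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            h, w = rng.integers(5, 17, size=2)
            green = rng.choice([10.0, 200.0, 4000.0], size=(h, w))
            red = rng.choice([10.0, 500.0, 4000.0], size=(h, w))
            conn = int(rng.choice([4, 8]))
            min_area = int(rng.integers(1, 3))
            cfg = _tiny_config(connectivity=conn, min_puncta_area_px=min_area,
                               tissue_threshold_value=100.0)
            micro = Micrograph(green=green, red=red, pixel_size_um=0.1)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                dets = detect_mitolysosomes(micro, cfg)
            oracle = brute_force_detect(
                green, red, 100.0, cfg.ratio_epsilon, cfg.ratio_threshold,
                cfg.red_threshold_value, min_area, conn,
            )
            assert len(dets) == len(oracle)
            for comp, opix in zip(dets.components, oracle):
                oc = (
                    sum(p[0] for p in opix) / len(opix),
                    sum(p[1] for p in opix) / len(opix),
                )
                assert comp.area_px == len(opix)
                assert (comp.centroid_row, comp.centroid_col) == pytest.approx(oc)

    def test_restrict_mask_uses_centroid_rule(self):
        green = np.full((10, 10), 1000.0)
        red = np.full((10, 10), 1000.0)
        # 3-px horizontal punctum spanning columns 4-6; centroid at col 5
        for x in (4, 5, 6):
            green[5, x] = 10.0
            red[5, x] = 3000.0
        micro = Micrograph(green=green, red=red, pixel_size_um=0.1)
        left = np.zeros((10, 10), dtype=bool)
        left[:, :6] = True  # centroid col 5 inside
        right = ~left  # centroid outside
        cfg = _tiny_config()
        assert len(detect_mitolysosomes(micro, cfg, restrict_mask=left)) == 1
        assert len(detect_mitolysosomes(micro, cfg, restrict_mask=right)) == 0


class TestMetrics:
    def _detections(self, n, area_px, px_um=0.1):
        comps = [
            Component(area_px=area_px, area_um2=area_px * px_um**2,
                      centroid_row=float(i), centroid_col=0.0, mean_ratio=5.0, mean_red=1.0)
            for i in range(n)
        ]
        return MitolysosomeSet(comps, image_id="img0")

    def test_direct_arithmetic_example(self):
        # 10 puncta of 20 px^2, mask 1e6 px, 0.1 um pixels -> 0.01 mm^2 tissue
        mask = np.ones((1000, 1000), dtype=bool)
        m = compute_metrics(self._detections(10, 20), mask, 0.1)
        assert m.tissue_area_mm2 == pytest.approx(0.01)
        assert m.count_per_mm2 == pytest.approx(1000.0)
        assert m.occupied_percent == pytest.approx(0.02)

    def test_zero_detections(self):
        m = compute_metrics(MitolysosomeSet([], "e"), np.ones((10, 10), bool), 0.1)
        assert (m.count_per_mm2, m.occupied_percent) == (0.0, 0.0)

    def test_empty_mask_error_names_image(self):
        with pytest.raises(ValueError, match="img0"):
            compute_metrics(self._detections(1, 5), np.zeros((5, 5), bool), 0.1)

    def test_occupied_percent_bounded(self, noiseless_scene, default_config):
        img, _ = noiseless_scene
        _, met = quantify_image(img, default_config)
        assert 0.0 <= met.occupied_percent <= 100.0


class TestAggregation:
    MANIFEST = pd.DataFrame(
        {
            "image_id": ["i1", "i2", "i3"],
            "animal_id": ["a1", "a1", "a2"],
            "PINK1": ["WT", "WT", "KO"],
            "POLG": ["WT", "WT", "WT"],
        }
    )

    def _metrics(self, pairs):
        return pd.DataFrame(
            [
                {
                    "image_id": iid,
                    "count_per_mm2": v,
                    "occupied_percent": v / 10,
                    "tissue_area_mm2": 0.01,
                    "n_components": 1,
                }
                for iid, v in pairs
            ]
        )

    def test_mean_across_images(self):
        out = aggregate_per_animal(self._metrics([("i1", 4.0), ("i2", 6.0), ("i3", 9.0)]), self.MANIFEST)
        a1 = out.loc[out["animal_id"] == "a1"].iloc[0]
        assert a1["count_per_mm2"] == 5.0 and a1["n_images"] == 2

    def test_single_image_passthrough_and_order_invariance(self):
        m = self._metrics([("i1", 4.0), ("i2", 6.0), ("i3", 9.0)])
        out1 = aggregate_per_animal(m, self.MANIFEST)
        out2 = aggregate_per_animal(m.iloc[::-1].reset_index(drop=True), self.MANIFEST)
        pd.testing.assert_frame_equal(out1, out2)
        assert out1.loc[out1["animal_id"] == "a2", "count_per_mm2"].iloc[0] == 9.0

    def test_animal_without_images_warns(self):
        manifest = pd.concat(
            [self.MANIFEST, pd.DataFrame([{"image_id": "i9", "animal_id": "a3",
                                           "PINK1": "KO", "POLG": "WT"}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="zero images"):
            out = aggregate_per_animal(self._metrics([("i1", 4.0), ("i2", 6.0), ("i3", 9.0)]), manifest)
        assert "a3" not in set(out["animal_id"])
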