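"""Confocal scenes, segmentation, spot metrics, normalization, ANOVA."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nanocorona import (
    ConfocalSceneConfig,
    InputError,
    generate_confocal_scene,
    percent_change_series,
    retention_trajectory,
    segment_scene,
    simulate_time_course,
    spot_metrics,
    two_way_anova,
)
from nanocorona.confocal import CONFOCAL_PRESETS

from oracles import cell_means_anova


@pytest.fixture
def scene():
    cfg = ConfocalSceneConfig(lyso_overlap=0.60, seed=1)
    image, masks = generate_confocal_scene(cfg)
    return cfg, image, masks


class TestSceneGeneration:
    def test_zero_retention_leaves_background_only(self):
        cfg = ConfocalSceneConfig(retention=0.0, seed=2)
        image, masks = generate_confocal_scene(cfg)
        assert np.all(image[1][masks["spots"] > 0] == cfg.background)

    def test_lysosome_overlap_constructed_to_one_pixel(self, scene):
        """Planted overlap 0.60: per-spot pixel-counted overlap within one
        pixel of the target."""
        cfg, image, masks = scene
        spots = masks["spots"]
        for sid in range(1, spots.max() + 1):
            spot = spots == sid
            overlap = (spot & masks["lysosomes"]).sum()
            assert abs(overlap - 0.60 * spot.sum()) <= 2.0

    def test_two_cells_give_two_components(self):
        from skimage.measure import label

        cfg = ConfocalSceneConfig(n_cells=2, seed=3)
        _, masks = generate_confocal_scene(cfg)
        assert label(masks["cells"], connectivity=2).max() == 2

    def test_determinism(self):
        cfg = ConfocalSceneConfig(seed=9, noise_sigma=5.0)
        img1, _ = generate_confocal_scene(cfg)
        img2, _ = generate_confocal_scene(cfg)
        np.testing.assert_array_equal(img1, img2)


class TestSegmentation:
    def test_recovers_planted_spot_count(self, scene):
        cfg, image, masks = scene
        seg = segment_scene(image)
        assert seg.n_spots == masks["spots"].max()

    def test_spot_outside_cells_excluded(self):
        """A reflectance spot planted outside every cell is not counted."""
        cfg = ConfocalSceneConfig(seed=4)
        image, masks = generate_confocal_scene(cfg)
        baseline = segment_scene(image).n_spots
        from skimage.draw import disk

        rr, cc = disk((10, 10), 6, shape=image.shape[1:])
        outside = ~masks["cells"][rr, cc].any()
        assert outside
        image[2][rr, cc] += cfg.spot_intensity
        assert segment_scene(image).n_spots == baseline

    def test_spot_straddling_cell_edge_keeps_interior_half(self):
        """Mask-intersection semantics: only the in-cell part survives."""
        cfg = ConfocalSceneConfig(n_cells=1, seed=5)
        image, masks = generate_confocal_scene(cfg)
        from skimage.draw import disk
        from skimage.measure import label

        # place a spot centred on the cell boundary
        cell_rows, cell_cols = np.nonzero(masks["cells"])
        edge = (int(cell_rows.max()), int(cell_cols[cell_rows.argmax()]))
        rr, cc = disk(edge, 6, shape=image.shape[1:])
        image[2][rr, cc] += cfg.spot_intensity
        seg = segment_scene(image)
        planted = np.zeros(image.shape[1:], dtype=bool)
        planted[rr, cc] = True
        recovered = (seg.spot_labels > 0) & planted
        inside = planted & masks["cells"]
        np.testing.assert_array_equal(recovered, inside)
        assert 0 < inside.sum() < planted.sum()

    def test_blank_channel_flagged(self):
        image = np.zeros((4, 64, 64))
        seg = segment_scene(image)
        assert seg.n_spots == 0
        assert any("blank" in f for f in seg.flags)


class TestSpotMetrics:
    def test_constant_corona_intensity_exact(self, scene):
        """Noise-free: mean corona on spots equals background + planted
        intensity x retention exactly."""
        cfg, image, masks = scene
        seg = segment_scene(image)
        metrics = spot_metrics(image, seg, cfg.pixel_size_nm)
        planted = cfg.background + cfg.corona_intensity * cfg.retention
        assert metrics["mean_corona_intensity"] == planted
        assert metrics["corona_intensity_bgsub"] == pytest.approx(
            cfg.corona_intensity * cfg.retention
        )

    def test_equivalent_diameter_of_rasterized_disk(self):
        """One planted disk of radius 10 px at 100 nm/px: equivalent diameter
        within half a pixel of 2000 nm."""
        cfg = ConfocalSceneConfig(
            n_cells=1, n_spots_per_cell=1, spot_radius_px=10, seed=6
        )
        image, _ = generate_confocal_scene(cfg)
        seg = segment_scene(image)
        metrics = spot_metrics(image, seg, cfg.pixel_size_nm)
        assert metrics["n_spots"] == 1
        assert abs(metrics["mean_equivalent_diameter_nm"] - 2000.0) <= 50.0

    def test_lysosomal_colocalization_recovered(self, scene):
        """Planted overlap 0.60 reported as 60 +- 2 percentage points."""
        cfg, image, masks = scene
        seg = segment_scene(image)
        metrics = spot_metrics(image, seg, cfg.pixel_size_nm)
        assert metrics["lysosomal_colocalization_pct"] == pytest.approx(60.0, abs=2.0)

    def test_no_spots_flagged(self):
        cfg = ConfocalSceneConfig(seed=7)
        image, _ = generate_confocal_scene(cfg)
        image[2][:] = cfg.background  # erase the reflectance signal
        seg = segment_scene(image)
        metrics = spot_metrics(image, seg, cfg.pixel_size_nm)
        assert metrics["n_spots"] == 0
        assert "no spots" in metrics["flags"]
        assert metrics["mean_corona_intensity"] == 0.0

    def test_coloc_invariant_to_corona_rescaling(self, scene):
        """Scaling the corona channel does not move mask-based metrics."""
        cfg, image, masks = scene
        seg = segment_scene(image)
        m1 = spot_metrics(image, seg, cfg.pixel_size_nm)
        scaled = image.copy()
        scaled[1] *= 7.3
        m2 = spot_metrics(scaled, seg, cfg.pixel_size_nm)
        assert m1["lysosomal_colocalization_pct"] == m2["lysosomal_colocalization_pct"]
        assert m1["total_spot_area_um2"] == m2["total_spot_area_um2"]


class TestPercentChange:
    def test_constant_series_all_zero(self):
        pc = percent_change_series([5.0, 5.0, 5.0])
        assert np.all(pc.deltas == 0)
        assert np.all(pc.log_ratios == 0)
        assert pc.cumulative_decrease == 0.0

    def test_worked_decrease_series(self):
        """Series (100, 80, 56.82) shows a cumulative decrease of 43.18%."""
        pc = percent_change_series([100.0, 80.0, 56.82])
        assert pc.cumulative_decrease == pytest.approx(43.18)
        assert pc.deltas[0] == pytest.approx(-20.0)

    def test_halving_interval(self):
        pc = percent_change_series([10.0, 5.0])
        assert pc.deltas[0] == pytest.approx(-50.0)
        assert pc.log_ratios[0] == pytest.approx(np.log(0.5))

    def test_log_branch_error_keeps_deltas(self):
        pc = percent_change_series([10.0, -5.0])
        assert pc.log_ratios is None and pc.log_error is not None
        assert pc.deltas[0] == pytest.approx(-150.0)

    def test_retention_trajectory_realizes_configured_decrease(self):
        for preset in CONFOCAL_PRESETS.values():
            r = retention_trajectory(preset["decrease_pct"], 5)
            pc = percent_change_series(r)
            assert pc.cumulative_decrease == pytest.approx(preset["decrease_pct"])


class TestTimeCourse:
    def test_declining_and_flat_presets(self):
        """Measured corona trajectories follow the coating presets:
        declining for uncoated/PVP, near flat for F127/AA4040."""
        rng = np.random.default_rng(0)
        for material, declining in [("TiO2-un", True), ("TiO2-AA4040", False)]:
            tc = simulate_time_course(material, rng=rng)
            pc = percent_change_series(tc["corona_intensity_bgsub"].to_numpy())
            if declining:
                assert pc.cumulative_decrease > 20.0
                assert np.all(pc.deltas < 0)
            else:
                assert abs(pc.cumulative_decrease) < 10.0

    def test_one_row_per_time_point(self):
        tc = simulate_time_course("TiO2-PVP", times_h=(0, 6, 18))
        assert list(tc["time_h"]) == [0.0, 6.0, 18.0]
        assert (tc["n_spots"] > 0).all()


class TestTwoWayAnova:
    @staticmethod
    def _random_balanced(rng, a=3, b=4, r=3):
        rows = []
        for ai in range(a):
            for bi in range(b):
                for _ in range(r):
                    rows.append(
                        {
                            "material": f"m{ai}",
                            "time_h": float(bi),
                            "value": rng.normal(ai * 2.0 + bi, 1.0),
                        }
                    )
        return pd.DataFrame(rows)

    def test_sum_of_squares_identity_and_cell_means_oracle(self, rng):
        """SS_A + SS_B + SS_AB + SS_within = SS_total to 1e-9 relative, and
        F ratios match the independent cell-means oracle."""
        df = self._random_balanced(rng)
        result = two_way_anova(df)
        ss = result["ss"]
        assert ss["A"] + ss["B"] + ss["AB"] + ss["within"] == pytest.approx(
            ss["total"], rel=1e-9
        )
        oracle = cell_means_anova(df["value"], df["material"], df["time_h"])
        for key in ("A", "B", "AB"):
            assert result["F"][key] == pytest.approx(oracle["F"][key], rel=1e-9)

    def test_matches_statsmodels(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = self._random_balanced(rng, a=2, b=3, r=4)
        result = two_way_anova(df)
        fit = smf.ols("value ~ C(material) * C(time_h)", data=df).fit()
        table = anova_lm(fit, typ=2)
        assert result["F"]["A"] == pytest.approx(table.loc["C(material)", "F"], rel=1e-8)
        assert result["F"]["B"] == pytest.approx(table.loc["C(time_h)", "F"], rel=1e-8)
        assert result["F"]["AB"] == pytest.approx(
            table.loc["C(material):C(time_h)", "F"], rel=1e-8
        )
        assert result["p"]["AB"] == pytest.approx(
            table.loc["C(material):C(time_h)", "PR(>F)"], rel=1e-6
        )

    def test_additive_effects_zero_interaction(self):
        """A 2x2 design with additive effects and replicate-level jitter that
        cancels per cell has interaction SS 0 to 1e-9."""
        rows = []
        for ai, a_eff in enumerate([0.0, 3.0]):
            for bi, b_eff in enumerate([0.0, 5.0]):
                for jitter in (-1.0, 1.0):
                    rows.append(
                        {"material": ai, "time_h": bi, "value": 10 + a_eff + b_eff + jitter}
                    )
        result = two_way_anova(pd.DataFrame(rows))
        assert result["ss"]["AB"] == pytest.approx(0.0, abs=1e-9)

    def test_all_equal_reports_no_variance(self):
        df = pd.DataFrame(
            {"material": [0, 0, 1, 1] * 2, "time_h": [0, 0, 0, 0, 1, 1, 1, 1],
             "value": [4.0] * 8}
        )
        result = two_way_anova(df)
        assert result["no_variance"]
        assert np.isnan(result["F"]["A"])

    def test_unbalanced_design_rejected(self, rng):
        df = self._random_balanced(rng).iloc[:-1]
        with pytest.raises(InputError, match="balanced"):
            two_way_anova(df)
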