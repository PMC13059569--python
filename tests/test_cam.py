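import numpy as np
import pytest

from nucleoprofiler.cam import (BATTERY_VERSION, FEATURE_CATEGORIES,
                                CamHeatmap, align_and_average, align_heatmap,
                                cam_feature_battery, nuclear_intensity,
                                periphery_enrichment, score_cam)
from nucleoprofiler.geometry import (EllipseFit, ZonePartition,
                                     elliptical_radius, partition_zones)

from conftest import rasterize_ellipse


class _StubModel:
    """Minimal Score-CAM target: fixed activation maps, deterministic logit."""

    def __init__(self, maps, logit_fn):
        self.maps = np.asarray(maps, dtype=np.float32)

        self.logit_fn = logit_fn

    def forward(self, x, train=False, return_activations=False):
        logits = np.array([self.logit_fn(xi) for xi in x], dtype=np.float64)
        if return_activations:
            acts = np.repeat(self.maps[None], x.shape[0], axis=0)
            return logits, acts
        return logits


def ellipse_partition(a=30.0, b=20.0, shape=(80, 80), center=(40.0, 40.0),
                      theta=0.0):
    ell = EllipseFit(center=center, semi_major=a, semi_minor=b,
                     orientation=theta)
    return ell, partition_zones(ell, shape)


class TestScoreCam:
    def test_single_map_returns_normalized_map_exactly(self):
        h = w = 16
        rng = np.random.default_rng(0)
        m = rng.uniform(-3, 5, (1, h, w))
        model = _StubModel(m, lambda xi: float(xi.sum()))
        image = rng.uniform(0, 1, (3, h, w)).astype(np.float32)
        heat = score_cam(model, image, np.ones((h, w), bool))
        expected = (m[0] - m[0].min()) / (m[0].max() - m[0].min())
        assert np.allclose(heat.scores, expected, atol=1e-6)

    def test_heatmap_is_convex_combination_of_maps(self):
        h = w = 12
        rng = np.random.default_rng(1)
        maps = rng.uniform(0, 1, (4, h, w))
        model = _StubModel(maps, lambda xi: float(xi.mean()))
        image = rng.uniform(0, 1, (3, h, w)).astype(np.float32)
        heat = score_cam(model, image, np.ones((h, w), bool)).scores
        norm = np.stack([(m - m.min()) / (m.max() - m.min()) for m in maps])
        assert (heat >= norm.min(axis=0) - 1e-9).all()
        assert (heat <= norm.max(axis=0) + 1e-9).all()
        assert (heat >= 0).all()

    def test_target_class_flips_weighting(self):
        h = w = 12
        rng = np.random.default_rng(2)
        maps = rng.uniform(0, 1, (2, h, w))
        # logit kept in sigmoid's sensitive range so the two masked passes
        # produce distinct scores (and therefore distinct softmax weights)
        model = _StubModel(maps, lambda xi: float(xi[0].mean()) * 8.0 - 2.0)
        image = rng.uniform(0, 1, (3, h, w)).astype(np.float32)
        heat1 = score_cam(model, image, np.ones((h, w), bool),
                          target_class=1).scores
        heat0 = score_cam(model, image, np.ones((h, w), bool),
                          target_class=0).scores
        assert not np.allclose(heat1, heat0)

    def test_constant_map_skipped_with_warning(self):
        h = w = 10
        rng = np.random.default_rng(3)
        maps = np.stack([np.full((h, w), 2.0), rng.uniform(0, 1, (h, w))])
        model = _StubModel(maps, lambda xi: float(xi.mean()))
        image = rng.uniform(0, 1, (3, h, w)).astype(np.float32)
        with pytest.warns(UserWarning, match="constant"):
            heat = score_cam(model, image, np.ones((h, w), bool))
        m = maps[1]
        assert np.allclose(heat.scores, (m - m.min()) / (m.max() - m.min()),
                           atol=1e-6)

    def test_all_constant_maps_give_zero_heatmap(self):
        h = w = 8
        maps = np.stack([np.full((h, w), 1.0), np.full((h, w), 3.0)])
        model = _StubModel(maps, lambda xi: 0.0)
        with pytest.warns(UserWarning):
            heat = score_cam(model, np.zeros((3, h, w), np.float32),
                             np.ones((h, w), bool))
        assert (heat.scores == 0).all()

    def test_real_model_smoke(self):
        from nucleoprofiler.classifier import ModelSpec, build_model
        spec = ModelSpec(architecture="9conv_1f", input_size=32)
        model = build_model(spec, seed=0)
        rng = np.random.default_rng(4)
        image = rng.uniform(0, 1, (3, 32, 32)).astype(np.float32)
        mask = np.ones((32, 32), bool)
        heat = score_cam(model, image, mask)
        assert heat.scores.shape == (32, 32)
        assert (heat.scores >= 0).all()
        assert heat.scores.max() <= 1 + 1e-6

    def test_bad_input_shape_raises(self):
        model = _StubModel(np.zeros((1, 4, 4)), lambda xi: 0.0)
        with pytest.raises(ValueError):
            score_cam(model, np.zeros((4, 4)), np.ones((4, 4), bool))


class TestNuclearMetrics:
    def test_constant_heatmap_gives_constant(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        scores = np.where(mask, 3.5, 0.0)
        assert nuclear_intensity(CamHeatmap(scores, mask)) == 3.5

    def test_half_mask_nonzero_gives_one(self):
        # zeros inside the mask are excluded from M by definition
        mask = np.zeros((10, 20), bool)
        mask[:, :10] = True  # 100 mask px
        scores = np.zeros((10, 20))
        scores[:, :5] = 1.0  # 50 of them score 1.0, 50 score 0
        assert nuclear_intensity(CamHeatmap(scores, mask)) == 1.0

    def test_all_zero_scores_missing(self):
        mask = np.ones((8, 8), bool)
        assert nuclear_intensity(CamHeatmap(np.zeros((8, 8)), mask)) is None

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            nuclear_intensity(CamHeatmap(np.zeros((8, 8)),
                                         np.zeros((8, 8), bool)))

    def test_uniform_enrichment_is_one(self):
        ell, part = ellipse_partition()
        scores = np.where(part.interior_mask, 2.0, 0.0)
        hm = CamHeatmap(scores, part.interior_mask, ellipse=ell)
        assert periphery_enrichment(hm, part) == 1.0

    def test_two_level_fixture_closed_form(self):
        # 100 mask px of which 20 are part5; S = 1 on part5, 0.5 elsewhere
        # -> numerator 1.0, denominator 0.6, ratio 5/3
        labels = np.zeros((10, 10), dtype=int)
        labels[:, :] = 1
        labels[:2] = 5  # 20 periphery px
        part = ZonePartition(labels=labels,
                             areas=np.array([80, 0, 0, 0, 20], float),
                             ellipse=EllipseFit((5.0, 5.0), 5.0, 5.0, 0.0))
        scores = np.where(labels == 5, 1.0, 0.5)
        hm = CamHeatmap(scores, labels > 0)
        assert periphery_enrichment(hm, part) == pytest.approx(5 / 3,
                                                               abs=1e-9)

    def test_zero_periphery_gives_zero(self):
        ell, part = ellipse_partition()
        scores = np.where(part.interior_mask & ~part.zone_mask(5), 4.0, 0.0)
        hm = CamHeatmap(scores, part.interior_mask)
        assert periphery_enrichment(hm, part) == 0.0

    def test_zero_heatmap_enrichment_missing(self):
        ell, part = ellipse_partition()
        hm = CamHeatmap(np.zeros(part.labels.shape), part.interior_mask)
        assert periphery_enrichment(hm, part) is None


def radial_heatmap(shape, center, a, b, theta):
    """Smooth rho-symmetric test map exp(-2*rho^2).

    Defined on the whole canvas (not truncated at the ellipse boundary) so
    alignment accuracy is limited by interpolation of a smooth function, not
    by a boundary jump.
    """
    ell = EllipseFit(center=center, semi_major=a, semi_minor=b,
                     orientation=theta)
    rho = elliptical_radius(ell, shape)
    return CamHeatmap(np.exp(-2 * rho ** 2), rho <= 1.0, ellipse=ell)


class TestAlignment:
    def test_identity_alignment_on_canonical_ellipse(self):
        side = 341  # default output canvas for canonical axes (150, 100)
        c = side / 2.0
        hm = radial_heatmap((side, side), (c, c), 150.0, 100.0, np.pi / 2)
        aligned, amask = align_heatmap(hm)
        # rho-symmetric map: alignment is the identity up to interpolation.
        # The outermost frame pixels map to source coordinates exactly on
        # the frame edge, where float rounding can push them just outside
        # (filled with 0), so the comparison excludes a 2-px margin.
        assert np.abs(aligned - hm.scores)[2:-2, 2:-2].max() < 1e-3
        agree = (amask == hm.mask).mean()
        assert agree > 0.999

    def test_rotation_consistency(self):
        shape = (260, 260)
        hm_a = radial_heatmap(shape, (130.0, 130.0), 90.0, 55.0, 0.3)
        hm_b = radial_heatmap(shape, (130.0, 130.0), 90.0, 55.0, 1.9)
        al_a, _ = align_heatmap(hm_a)
        al_b, _ = align_heatmap(hm_b)
        assert np.abs(al_a - al_b).max() < 2e-2

    def test_average_of_identical_equals_single(self):
        shape = (260, 260)
        hm = radial_heatmap(shape, (130.0, 130.0), 80.0, 50.0, 0.7)
        single, _ = align_heatmap(hm)
        avg = align_and_average([hm, hm])
        assert np.allclose(avg, single)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            align_and_average([])

    def test_fitted_ellipse_used_when_absent(self):
        mask = rasterize_ellipse(40.0, 25.0, 0.0, (60.0, 60.0), (120, 120))
        hm = CamHeatmap(np.where(mask, 1.0, 0.0), mask)
        aligned, amask = align_heatmap(hm)
        assert hm.ellipse is not None  # populated by with_ellipse()
        assert amask.any()


class TestFeatureBattery:
    def make_heatmap(self):
        rng = np.random.default_rng(0)
        mask = rasterize_ellipse(30.0, 20.0, 0.2, (40.0, 40.0), (80, 80))
        scores = np.where(mask, rng.uniform(0.1, 1.0, (80, 80)), 0.0)
        return CamHeatmap(scores, mask)

    def test_battery_keys_match_category_map(self):
        feats = cam_feature_battery(self.make_heatmap())
        assert set(feats) == set(FEATURE_CATEGORIES)
        assert all(np.isfinite(v) for v in feats.values())
        assert BATTERY_VERSION == "1.0"

    def test_categories_cover_five_groups(self):
        assert set(FEATURE_CATEGORIES.values()) == {
            "Size", "Shape", "Intensity", "Edge", "Texture"}

    def test_uniform_heatmap_degenerate_features(self):
        mask = rasterize_ellipse(20.0, 15.0, 0.0, (30.0, 30.0), (60, 60))
        hm = CamHeatmap(np.where(mask, 0.8, 0.0), mask)
        feats = cam_feature_battery(hm)
        assert feats["intensity_sd"] == 0.0
        assert feats["intensity_mean"] == pytest.approx(0.8)
        assert feats["entropy"] == 0.0
        assert feats["canny_edge_count"] == 0.0

    def test_area_matches_mask(self):
        hm = self.make_heatmap()
        feats = cam_feature_battery(hm)
        assert feats["area"] == hm.mask.sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cam_feature_battery(CamHeatmap(np.zeros((10, 10)),
                                           np.zeros((10, 10), bool)))


def test_negative_scores_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        CamHeatmap(np.full((5, 5), -1.0), np.ones((5, 5), bool))
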