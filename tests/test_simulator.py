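import numpy as np
import pytest

from ringcorr import (
    SimulationConfig,
    ZoneMap,
    alternating_zone_map,
    backbone_from_mask,
    build_zone_map,
    make_kernel,
    render,
    simulate_pair,
    spawn_counts,
    synthetic_axon_mask,
)
from ringcorr.simulate import OFF_LINE, ON_LINE


class TestSyntheticAxonMask:
    def test_zero_curvature_is_straight_band(self):
        mask = synthetic_axon_mask(10.0, 0.5, curvature=0.0, seed=0)
        rows = np.nonzero(mask.any(axis=1))[0]
        # straight band: every column has the identical row support
        assert (mask[rows[0] : rows[-1] + 1].all(axis=0)).all()
        assert len(rows) == pytest.approx(50, abs=2)
        assert mask.sum() == pytest.approx(10 * 0.5 * 100 * 100, rel=0.05)

    def test_deterministic_from_seed(self):
        a = synthetic_axon_mask(seed=5)
        b = synthetic_axon_mask(seed=5)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, synthetic_axon_mask(seed=6))

    def test_too_small_mask_rejected(self):
        with pytest.raises(ValueError):
            synthetic_axon_mask(length_um=2.0)


class TestBackbone:
    def test_straight_band_backbone_is_midline(self, straight_band_mask):
        bb = backbone_from_mask(straight_band_mask)
        # Lee thinning retracts about half the band width from each end
        assert len(bb) >= 1000 - 50 - 6
        interior = bb[(bb[:, 1] > 40) & (bb[:, 1] < 960)]
        assert np.all(np.abs(interior[:, 0] - 24.5) <= 1.0)

    def test_plus_shape_keeps_longer_bar(self):
        mask = np.zeros((41, 81), bool)
        mask[20, :] = True
        mask[10:31, 40] = True
        bb = backbone_from_mask(mask)
        assert bb[:, 1].min() == 0 and bb[:, 1].max() == 80

    def test_single_pixel_line_is_fixed_point(self):
        mask = np.zeros((5, 40), bool)
        mask[2, :] = True
        bb = backbone_from_mask(mask)
        assert len(bb) == 40
        assert np.all(bb[:, 0] == 2)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((10, 50), bool)
        mask[2, :20] = True
        mask[7, 30:] = True
        with pytest.raises(ValueError):
            backbone_from_mask(mask)


@pytest.fixture(scope="module")
def band_zones(straight_band_mask):
    bb = backbone_from_mask(straight_band_mask)
    base = build_zone_map(straight_band_mask, bb, 200.0, 2, 100.0)
    shifted = alternating_zone_map(straight_band_mask, bb, 200.0, 100.0, 2, 100.0)
    return base, shifted


class TestZoneMaps:
    def test_zones_partition_mask(self, straight_band_mask, band_zones):
        base, _ = band_zones
        np.testing.assert_array_equal(base.mask, straight_band_mask)
        assert not (base.on_line & base.off_line).any()

    def test_stripes_every_20_px_and_5_px_wide(self, band_zones):
        base, _ = band_zones
        on_cols = np.unique(np.nonzero(base.on_line)[1])
        runs = np.split(on_cols, np.nonzero(np.diff(on_cols) > 1)[0] + 1)
        widths = {len(r) for r in runs}
        assert widths == {5}  # halfwidth 2 -> 5 px stripes
        centres = np.array([r[2] for r in runs])
        assert set(np.diff(centres)) == {20}

    def test_area_ratio_near_quarter(self, band_zones):
        base, _ = band_zones
        ratio = base.area_on / (base.area_on + base.area_off)
        assert ratio == pytest.approx(5 / 20, abs=0.02)

    def test_alternating_offset_half_period(self, band_zones):
        base, shifted = band_zones
        c0 = np.unique(np.nonzero(base.on_line)[1])[:5]
        c1 = np.unique(np.nonzero(shifted.on_line)[1])[:5]
        np.testing.assert_array_equal(c1 - c0, 10)
        assert not (base.on_line & shifted.on_line).any()

    def test_full_period_shift_is_identity_modulo_ends(
        self, straight_band_mask, band_zones
    ):
        base, _ = band_zones
        bb = backbone_from_mask(straight_band_mask)
        wrapped = build_zone_map(
            straight_band_mask, bb, 200.0, 2, 100.0, offset_nm=200.0
        )
        # interior stripes coincide; only the ends may differ
        interior = np.zeros_like(straight_band_mask)
        interior[:, 60:940] = True
        np.testing.assert_array_equal(
            base.on_line & interior, wrapped.on_line & interior
        )


def _dummy_zone_map(a_on, a_off):
    zones = np.zeros((200, 100), dtype=np.int8)
    flat = zones.ravel()
    flat[:a_on] = ON_LINE
    flat[a_on : a_on + a_off] = OFF_LINE
    return ZoneMap(zones=zones, backbone=np.zeros((2, 2)), spacing_nm=200.0)


class TestSpawnCounts:
    def test_total_from_density(self):
        zm = _dummy_zone_map(5000, 15000)
        counts = spawn_counts(zm, SimulationConfig(plp=50.0))
        assert counts.p_total == 200  # D=100, A=20000 px, PPM^2=10000

    def test_plp_100_puts_everything_on_line(self):
        zm = _dummy_zone_map(5000, 15000)
        counts = spawn_counts(zm, SimulationConfig(plp=100.0))
        assert counts.p_on == counts.p_total
        assert counts.p_off == 0

    def test_plp_50_reduces_to_area_proportion(self):
        zm = _dummy_zone_map(5000, 15000)
        counts = spawn_counts(zm, SimulationConfig(plp=50.0))
        assert (counts.p_on, counts.p_off) == (50, 150)

    def test_conservation(self):
        zm = _dummy_zone_map(3333, 11111)
        for plp in (50, 63, 87.5, 100):
            c = spawn_counts(zm, SimulationConfig(plp=plp))
            assert c.p_on + c.p_off == c.p_total

    def test_plp_range_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(plp=40.0)


class TestKernel:
    def test_unit_peak_at_centre(self):
        k = make_kernel("RED", 100.0)
        assert k.max() == pytest.approx(1.0)
        assert k[k.shape[0] // 2, k.shape[1] // 2] == 1.0

    def test_red_support_smaller_than_orange(self):
        red = make_kernel("RED", 100.0)
        orange = make_kernel("ORANGE", 100.0)
        assert red.shape[0] < orange.shape[0]

    def test_integral_matches_gaussian_closed_form(self):
        k = make_kernel("RED", 100.0)
        sigma = 60.0 / 1000.0 * 100.0 / (2 * np.sqrt(2 * np.log(2)))
        assert k.sum() == pytest.approx(2 * np.pi * sigma**2, rel=0.01)

    def test_sub_resolution_kernel_rejected(self):
        with pytest.raises(ValueError):
            make_kernel("RED", 10.0)  # 60 nm at 10 px/um is < 1 px FWHM


class TestRender:
    def test_single_point_reproduces_kernel(self):
        zones = np.zeros((41, 41), dtype=np.int8)
        zones[20, 20] = ON_LINE
        zm = ZoneMap(zones=zones, backbone=np.zeros((2, 2)), spacing_nm=200.0)
        cfg = SimulationConfig()
        from ringcorr.simulate import SpawnCounts

        counts = SpawnCounts(p_total=1, p_on=1, p_off=0, a_on=1, a_off=0)
        img = render(zm, counts, cfg, np.random.default_rng(0))
        k = make_kernel(cfg.kernel, cfg.pixels_per_um)
        r = k.shape[0] // 2
        np.testing.assert_allclose(
            img[20 - r : 20 + r + 1, 20 - r : 20 + r + 1], k, atol=1e-9
        )

    def test_no_noise_background_exact_zero(self, straight_band_mask):
        bb = backbone_from_mask(straight_band_mask)
        zm = build_zone_map(straight_band_mask, bb, 200.0, 2, 100.0)
        cfg = SimulationConfig(plp=100.0)
        img = render(zm, spawn_counts(zm, cfg), cfg, np.random.default_rng(1))
        assert img.min() >= 0.0
        # far corner never receives kernel mass
        assert img[0, 0] == 0.0

    def test_noise_std_matches_configuration(self):
        zones = np.zeros((150, 150), dtype=np.int8)
        zm = ZoneMap(zones=zones, backbone=np.zeros((2, 2)), spacing_nm=200.0)
        from ringcorr.simulate import SpawnCounts

        counts = SpawnCounts(0, 0, 0, 0, 0)
        cfg = SimulationConfig(noise_pct=10.0)
        img = render(zm, counts, cfg, np.random.default_rng(2))
        assert img.std() == pytest.approx(0.10, rel=0.15)  # >=10^4 px sample

    def test_budget_exceeding_zone_rejected(self):
        zm = _dummy_zone_map(10, 10)
        from ringcorr.simulate import SpawnCounts

        with pytest.raises(ValueError):
            render(
                zm,
                SpawnCounts(30, 20, 10, 10, 10),
                SimulationConfig(),
                np.random.default_rng(0),
            )


class TestSimulatePair:
    def test_same_seed_reproduces_pair(self, short_axon_mask):
        cfg = SimulationConfig()
        img_a, truth_a = simulate_pair(short_axon_mask, cfg, "alternating", 80, 80, seed=9)
        img_b, truth_b = simulate_pair(short_axon_mask, cfg, "alternating", 80, 80, seed=9)
        np.testing.assert_array_equal(img_a.channels[0], img_b.channels[0])
        np.testing.assert_array_equal(img_a.channels[1], img_b.channels[1])
        assert truth_a == truth_b

    def test_overlapping_channels_share_stripes(self, short_axon_mask):
        from ringcorr.validate import prepare_zone_maps

        cfg = SimulationConfig()
        base, shifted = prepare_zone_maps(short_axon_mask, cfg)
        img, truth = simulate_pair(
            short_axon_mask, cfg, "overlapping", 100, 100, seed=3,
            zone_maps=(base, shifted),
        )
        # at plp 100 every point spawns inside the on-line stripes, so the
        # mean intensity there dwarfs the anti-phase stripe set (the kernel
        # still spreads some mass into the inter-stripe gaps)
        for ch in img.channels:
            own = ch[base.on_line].mean()
            other = ch[shifted.on_line].mean()
            assert own > 3 * other

    def test_alternating_channels_use_offset_stripes(self, short_axon_mask):
        from ringcorr.validate import prepare_zone_maps

        cfg = SimulationConfig()
        base, shifted = prepare_zone_maps(short_axon_mask, cfg)
        img, _ = simulate_pair(
            short_axon_mask, cfg, "alternating", 100, 100, seed=3,
            zone_maps=(base, shifted),
        )
        ch2 = img.channels[1]
        assert ch2[shifted.on_line].mean() > 3 * ch2[base.on_line].mean()
        ch1 = img.channels[0]
        assert ch1[base.on_line].mean() > 3 * ch1[shifted.on_line].mean()

    def test_invalid_pattern_rejected(self, short_axon_mask):
        with pytest.raises(ValueError):
            simulate_pair(short_axon_mask, SimulationConfig(), "diagonal")


class TestSpawnUniformityAtChance:
    def test_plp_50_spawns_proportionally_to_area(self, straight_band_mask):
        """At PLP 50 the per-zone point budget is area-proportional, so the
        realized density is uniform across zones (chi-square over seeds)."""
        from scipy.stats import chisquare

        bb = backbone_from_mask(straight_band_mask)
        zm = build_zone_map(straight_band_mask, bb, 200.0, 2, 100.0)
        cfg = SimulationConfig(plp=50.0, point_density=300.0)
        counts = spawn_counts(zm, cfg)
        expected_ratio = zm.area_on / (zm.area_on + zm.area_off)
        observed = np.array([counts.p_on, counts.p_off], dtype=float)
        expected = observed.sum() * np.array([expected_ratio, 1 - expected_ratio])
        assert chisquare(observed, expected).pvalue > 0.01
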