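"""Circularity, fascicle reclassification, composition, deviation index."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw

from neuromorph.morphometry import (
    MorphometryConfig,
    component_roundness,
    normalized_deviation_index,
    quantify_composition,
    reclassify_fascicles,
)
from neuromorph.tissue import TissueClass


def _disk_mask(radius, pad=5):
    n = 2 * (radius + pad)
    m = np.zeros((n, n), dtype=bool)
    rr, cc = draw.disk((n / 2, n / 2), radius)
    m[rr, cc] = True
    return m


class TestRoundness:
    def test_large_disk_near_one(self):
        assert component_roundness(_disk_mask(100)) >= 0.95

    def test_square_near_analytic_pi_over_4(self):
        m = np.zeros((120, 120), dtype=bool)
        m[10:110, 10:110] = True
        assert component_roundness(m) == pytest.approx(np.pi / 4, abs=0.05)

    def test_thin_bar_low(self):
        m = np.zeros((20, 120), dtype=bool)
        m[10, 10:110] = True
        assert component_roundness(m) < 0.2

    def test_single_pixel_defined_as_one(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert component_roundness(m) == 1.0

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            component_roundness(np.zeros((4, 4), dtype=bool))

    def test_clamped_to_unit_interval(self, rng):
        for _ in range(20):
            m = rng.random((24, 24)) > 0.6
            if not m.any():
                continue
            assert 0.0 <= component_roundness(m) <= 1.0


class TestReclassify:
    def test_round_disk_rescued_to_organized(self):
        mask = np.full((80, 80), int(TissueClass.CONNECTIVE), dtype=np.uint8)
        rr, cc = draw.disk((40, 40), 20)
        mask[rr, cc] = TissueClass.UNORGANIZED_NERVOUS
        refined, comps = reclassify_fascicles(mask)
        assert (refined[rr, cc] == TissueClass.ORGANIZED_NERVOUS).all()
        assert len(comps) == 1 and comps[0].roundness >= 0.6

    def test_star_demoted_to_unorganized(self):
        mask = np.full((120, 120), int(TissueClass.CONNECTIVE), dtype=np.uint8)
        t = np.linspace(0, 2 * np.pi, 17)[:-1]
        r = np.where(np.arange(16) % 2 == 0, 40, 15)
        rr, cc = draw.polygon(60 + r * np.sin(t), 60 + r * np.cos(t), (120, 120))
        mask[rr, cc] = TissueClass.ORGANIZED_NERVOUS
        refined, comps = reclassify_fascicles(mask)
        assert (refined[rr, cc] == TissueClass.UNORGANIZED_NERVOUS).all()
        assert comps[0].roundness < 0.6

    def test_no_nervous_pixels_passthrough(self):
        mask = np.full((30, 30), int(TissueClass.ADIPOSE), dtype=np.uint8)
        refined, comps = reclassify_fascicles(mask)
        np.testing.assert_array_equal(refined, mask)
        assert comps == []

    def test_speckle_reassigned_to_connective_conserving_tissue(self):
        mask = np.full((40, 40), int(TissueClass.CONNECTIVE), dtype=np.uint8)
        mask[5:7, 5:7] = TissueClass.ORGANIZED_NERVOUS  # 4 px < 50
        rr, cc = draw.disk((25, 25), 10)
        mask[rr, cc] = TissueClass.ORGANIZED_NERVOUS
        before_tissue = int((mask != 0).sum())
        refined, comps = reclassify_fascicles(mask)
        assert (refined[5:7, 5:7] == TissueClass.CONNECTIVE).all()
        assert len(comps) == 1
        assert int((refined != 0).sum()) == before_tissue

    def test_nervous_pixel_count_conserved_above_threshold(self, rng):
        config = MorphometryConfig(min_component_px=0)
        mask = rng.choice([0, 1, 2, 3], size=(48, 48)).astype(np.uint8)
        refined, _ = reclassify_fascicles(mask, config)
        nerv = [int(TissueClass.ORGANIZED_NERVOUS), int(TissueClass.UNORGANIZED_NERVOUS)]
        assert np.isin(mask, nerv).sum() == np.isin(refined, nerv).sum()

    def test_connectivity_4_splits_diagonal_components(self):
        mask = np.full((20, 20), int(TissueClass.CONNECTIVE), dtype=np.uint8)
        mask[2:6, 2:6] = TissueClass.ORGANIZED_NERVOUS
        mask[6:10, 6:10] = TissueClass.ORGANIZED_NERVOUS  # touches diagonally
        cfg8 = MorphometryConfig(min_component_px=4, connectivity=8)
        cfg4 = MorphometryConfig(min_component_px=4, connectivity=4)
        _, comps8 = reclassify_fascicles(mask, cfg8)
        _, comps4 = reclassify_fascicles(mask, cfg4)
        assert len(comps8) == 1
        assert len(comps4) == 2


class TestComposition:
    def test_hand_counted_relative_areas(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask.flat[:40] = TissueClass.ORGANIZED_NERVOUS
        mask.flat[40:80] = TissueClass.UNORGANIZED_NERVOUS
        comp = quantify_composition(mask, mpp=1.0)
        assert comp.relative_area["organized_nervous"] == pytest.approx(0.5)
        assert comp.relative_area["unorganized_nervous"] == pytest.approx(0.5)

    def test_absolute_area_unit_conversion(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask.flat[:40] = TissueClass.ORGANIZED_NERVOUS
        mask.flat[40:80] = TissueClass.UNORGANIZED_NERVOUS
        comp = quantify_composition(mask, mpp=1.0)
        # 40 px at 1 um/px = 40 um^2 = 4e-5 mm^2
        assert comp.absolute_area_mm2["organized_nervous"] == pytest.approx(4e-5)

    def test_all_adipose(self):
        mask = np.full((8, 8), int(TissueClass.ADIPOSE), dtype=np.uint8)
        comp = quantify_composition(mask, mpp=0.5)
        assert comp.relative_area["adipose"] == 1.0
        assert all(
            v == 0.0 for k, v in comp.relative_area.items() if k != "adipose"
        )
        assert comp.deviation_index is None

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no non-background"):
            quantify_composition(np.zeros((8, 8), dtype=np.uint8), mpp=1.0)

    def test_nonpositive_mpp_rejected(self):
        mask = np.full((4, 4), 3, dtype=np.uint8)
        with pytest.raises(ValueError, match="mpp"):
            quantify_composition(mask, mpp=0.0)

    def test_erythrocyte_denominator_flag(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask.flat[:50] = TissueClass.CONNECTIVE
        mask.flat[50:100] = TissueClass.ERYTHROCYTE
        incl = quantify_composition(mask, mpp=1.0)
        excl = quantify_composition(
            mask, mpp=1.0,
            config=MorphometryConfig(include_erythrocytes_in_denominator=False),
        )
        assert incl.relative_area["connective"] == pytest.approx(0.5)
        assert excl.relative_area["connective"] == pytest.approx(1.0)

    def test_matches_brute_force_counting(self, rng):
        """Composition equals a naive per-pixel loop on random 32x32 masks."""
        for _ in range(25):
            mask = rng.integers(0, 6, size=(32, 32)).astype(np.uint8)
            comp = quantify_composition(mask, mpp=0.7)
            counts = {c: 0 for c in range(1, 6)}
            for r in range(32):
                for c in range(32):
                    if mask[r, c] != 0:
                        counts[int(mask[r, c])] += 1
            total = sum(counts.values())
            for cls, n in counts.items():
                name = TissueClass(cls).name.lower()
                assert comp.relative_area[name] == pytest.approx(n / total)
                assert comp.absolute_area_mm2[name] == pytest.approx(
                    n * 0.49 / 1e6
                )


class TestDeviationIndex:
    @pytest.mark.parametrize(
        "u, o, expected",
        [
            (0.5, 0.0, 1.0),
            (0.0, 0.5, -1.0),
            (0.3, 0.3, 0.0),
            (0.6, 0.2, (0.6 - 0.2) / 0.6),
        ],
    )
    def test_known_values(self, u, o, expected):
        assert normalized_deviation_index(u, o) == pytest.approx(expected)

    def test_undefined_when_no_nervous_tissue(self):
        assert normalized_deviation_index(0.0, 0.0) is None

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalized_deviation_index(-0.1, 0.2)

    @given(
        u=st.floats(0, 10, allow_nan=False, allow_subnormal=False),
        o=st.floats(0, 10, allow_nan=False, allow_subnormal=False),
        k=st.floats(1e-3, 1e3, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_scale_invariance_antisymmetry(self, u, o, k):
        d = normalized_deviation_index(u, o)
        if d is None:
            assert u == o == 0
            return
        assert -1.0 <= d <= 1.0
        assert normalized_deviation_index(k * u, k * o) == pytest.approx(d)
        assert normalized_deviation_index(o, u) == pytest.approx(-d)
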