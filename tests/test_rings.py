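"""Ring geometry: distance-map oracle equivalence, set identities,
annulus areas, contralateral referencing and fold statistics."""

from dataclasses import replace

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batperm.core import BinaryMask, SectionImage
from batperm.rings import (
    bat_mean_fold,
    build_rings,
    contralateral_reference,
    ring_statistics,
    signed_distance_map,
    signed_distance_map_bruteforce,
    territory_exclusions,
)
from batperm.segmentation import estimate_background, merge_clusters, tumor_mask
from batperm.synthetic import generate_section

from conftest import disc_mask, lesions_from_mask, random_blob


class TestSignedDistanceMap:
    def test_margin_pixels_are_zero(self):
        lesions = lesions_from_mask(disc_mask((64, 64), (32, 32), 15))
        d = signed_distance_map(lesions, 1)
        from batperm.segmentation import margin_mask

        npt.assert_allclose(d[margin_mask(lesions, 1)], 0.0)

    def test_disc_geometry_half_pixel(self):
        """Disc radius 100 um: a pixel 150 um from center sits at d ~ +50."""
        px = 1.0
        lesions = lesions_from_mask(disc_mask((320, 320), (160, 160), 100), px)
        d = signed_distance_map(lesions, 1)
        assert d[160, 160 + 150] == pytest.approx(50.0, abs=1.0)
        assert d[160, 160 + 50] == pytest.approx(-50.0, abs=1.0)

    def test_matches_bruteforce_on_random_blobs(self, rng):
        for _ in range(10):
            mask = random_blob(rng)
            lesions = lesions_from_mask(mask, max_gap=10.0)
            for k in lesions.lesion_ids:
                got = signed_distance_map(lesions, int(k))
                want = signed_distance_map_bruteforce(lesions, int(k))
                npt.assert_allclose(got, want, atol=1e-9)

    def test_empty_lesion_rejected(self):
        lesions = lesions_from_mask(disc_mask((32, 32), (16, 16), 5))
        with pytest.raises(KeyError):
            signed_distance_map(lesions, 99)


class TestBuildRings:
    def test_annulus_areas_match_circle_geometry(self):
        """Outward ring areas within 5% of the analytic annulus area."""
        px = 1.0
        r0 = 100.0
        lesions = lesions_from_mask(disc_mask((900, 900), (450, 450), int(r0)), px)
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 296.0, pixel_size=px)
        areas = rings.areas_um2
        for j in range(1, 11):  # first 10 outward rings
            idx = 37 + j - 1  # 37 inward bins precede the outward ones
            analytic = np.pi * ((r0 + 8 * j) ** 2 - (r0 + 8 * (j - 1)) ** 2)
            assert abs(areas[idx] - analytic) / analytic < 0.05

    def test_union_of_outward_rings_is_band_minus_exclusions(self, rng):
        mask = random_blob(rng, shape=(96, 96))
        lesions = lesions_from_mask(mask, max_gap=10.0)
        d = signed_distance_map(lesions, 1)
        excl = rng.random(d.shape) < 0.1
        rings = build_rings(d, 8.0, 96.0, exclusions=excl, pixel_size=1.0)
        outward = np.zeros_like(excl)
        for j in np.nonzero(rings.outward)[0]:
            outward |= rings.mask(int(j))
        npt.assert_array_equal(outward, (d > 0) & (d <= 96.0) & ~excl)

    def test_rings_pairwise_disjoint(self, rng):
        mask = random_blob(rng, shape=(96, 96))
        lesions = lesions_from_mask(mask, max_gap=10.0)
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 96.0, pixel_size=1.0)
        counts = np.zeros(rings.bin_index.shape, dtype=int)
        for j in range(rings.n_bins):
            counts += rings.mask(j).astype(int)
        assert counts.max() <= 1

    def test_extent_not_multiple_of_width_errors(self):
        lesions = lesions_from_mask(disc_mask((64, 64), (32, 32), 10))
        with pytest.raises(ValueError, match="multiple"):
            build_rings(signed_distance_map(lesions, 1), 8.0, 300.0)

    def test_excluding_everything_flags_all_rings(self):
        lesions = lesions_from_mask(disc_mask((64, 64), (32, 32), 10))
        d = signed_distance_map(lesions, 1)
        rings = build_rings(d, 8.0, 24.0, exclusions=np.ones_like(d, dtype=bool))
        assert rings.empty_bins.all()

    def test_outward_ring_areas_increase_for_convex_lesion(self):
        lesions = lesions_from_mask(disc_mask((400, 400), (200, 200), 60))
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 96.0, pixel_size=1.0)
        out_areas = rings.areas_um2[rings.outward]
        assert (np.diff(out_areas) > 0).all()


class TestContralateralReference:
    def _section(self, tracer, px=4.0):
        return SectionImage(channels={"tracer": tracer, "egfp": np.zeros_like(tracer)}, pixel_size=px)

    def test_uniform_field(self):
        px = 2.0
        mask = disc_mask((128, 256), (64, 60), 20)
        lesions = lesions_from_mask(mask, px)
        tracer = np.full((128, 256), 30.0)
        ref = contralateral_reference(self._section(tracer, px), lesions, 1, extent=96.0)
        assert ref == pytest.approx(30.0 / px**2)

    def test_synthetic_section_reference_within_2pct(self, noiseless_config):
        section, truth = generate_section(noiseless_config)
        lesions = lesions_from_mask(truth.lesion_labels > 0, noiseless_config.pixel_size)
        ref = contralateral_reference(section, lesions, 1)
        want = noiseless_config.tracer_background / noiseless_config.pixel_size**2
        assert abs(ref - want) / want < 0.02

    def test_contaminated_mirror_without_fallback_errors(self):
        # two lesions placed mirror-symmetrically: the reflection lands
        # inside the other lesion's territory
        px = 4.0
        mask = disc_mask((128, 256), (64, 60), 20) | disc_mask((128, 256), (64, 196), 20)
        lesions = lesions_from_mask(mask, px)
        tracer = np.full((128, 256), 30.0)
        with pytest.raises(ValueError, match="fallback"):
            contralateral_reference(self._section(tracer, px), lesions, 1, extent=96.0)

    def test_fallback_mask_used_when_mirror_contaminated(self):
        px = 4.0
        mask = disc_mask((128, 256), (64, 60), 20) | disc_mask((128, 256), (64, 196), 20)
        lesions = lesions_from_mask(mask, px)
        tracer = np.full((128, 256), 30.0)
        fb = np.zeros((128, 256), dtype=bool)
        fb[:10, 100:140] = True
        ref = contralateral_reference(
            self._section(tracer, px), lesions, 1, extent=96.0,
            fallback_mask=BinaryMask(fb, px),
        )
        assert ref == pytest.approx(30.0 / px**2)


class TestRingStatistics:
    def test_uniform_channel_fold_is_one(self):
        px = 2.0
        lesions = lesions_from_mask(disc_mask((128, 128), (64, 64), 20), px)
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 64.0, pixel_size=px)
        tracer = np.full((128, 128), 12.0)
        prof = ring_statistics(rings, tracer, reference=12.0 / px**2)
        npt.assert_allclose(prof.fold, 1.0)

    def test_noiseless_step_plateau_fold_exact(self, noiseless_config):
        cfg = replace(noiseless_config, bat_profile_kind="step")
        section, truth = generate_section(cfg)
        egfp = section.channels["egfp"]
        lesions = merge_clusters(
            tumor_mask(egfp, estimate_background(egfp), pixel_size=cfg.pixel_size)
        )
        rings = build_rings(
            signed_distance_map(lesions, 1), pixel_size=cfg.pixel_size
        )
        ref = contralateral_reference(section, lesions, 1)
        prof = ring_statistics(rings, section.channels["tracer"], ref)
        inside = prof.bin_hi <= 0
        npt.assert_allclose(prof.fold[inside], cfg.tumor_plateau_fold)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_fold_invariant_to_global_gain(self, scale):
        """Rescaling tracer and reference together leaves fold unchanged."""
        px = 2.0
        lesions = lesions_from_mask(disc_mask((96, 96), (48, 48), 15), px)
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 48.0, pixel_size=px)
        tracer = np.random.default_rng(1).uniform(5, 50, size=(96, 96))
        ref = 20.0 / px**2
        f1 = ring_statistics(rings, tracer, ref).fold
        f2 = ring_statistics(rings, tracer * scale, ref * scale).fold
        npt.assert_allclose(f1, f2, rtol=1e-9)

    def test_nonpositive_reference_rejected(self):
        lesions = lesions_from_mask(disc_mask((64, 64), (32, 32), 10))
        rings = build_rings(signed_distance_map(lesions, 1), 8.0, 24.0)
        with pytest.raises(ValueError):
            ring_statistics(rings, np.ones((64, 64)), reference=0.0)


class TestBatMeanFold:
    def _profile(self, folds, ref=1.0, width=8.0):
        from batperm.core import RadialProfile

        n = len(folds)
        lo = np.arange(n) * width
        return RadialProfile(
            bin_lo=lo,
            bin_hi=lo + width,
            n_pixels=np.full(n, 10),
            value=np.asarray(folds, dtype=float) * ref,
            units="au_per_um2",
            reference=ref,
        )

    def test_all_ones_is_one(self):
        assert bat_mean_fold(self._profile([1.0] * 12)) == pytest.approx(1.0)

    def test_constant_two_is_two(self):
        assert bat_mean_fold(self._profile([2.0] * 12)) == pytest.approx(2.0)

    def test_window_with_no_bins_errors(self):
        prof = self._profile([1.0] * 3, width=8.0)
        with pytest.raises(ValueError, match="window"):
            bat_mean_fold(prof, window=(200.0, 300.0))

    def test_window_excludes_ring_straddling_100um(self):
        """With 8-um rings the (96, 104] ring must not enter the window."""
        folds = [1.0] * 12 + [100.0]
        assert bat_mean_fold(self._profile(folds)) == pytest.approx(1.0)


class TestTerritoryExclusions:
    def test_single_lesion_has_no_exclusions(self):
        lesions = lesions_from_mask(disc_mask((64, 64), (32, 32), 10))
        assert not territory_exclusions(lesions, 1, 24.0).any()

    def test_other_lesion_tumor_always_excluded(self):
        mask = disc_mask((128, 400), (64, 80), 20) | disc_mask((128, 400), (64, 320), 20)
        lesions = lesions_from_mask(mask, 1.0)
        assert lesions.n_lesions == 2
        excl = territory_exclusions(lesions, 1, 96.0)
        assert excl[lesions.hull_mask(2)].all()
        assert not excl[lesions.hull_mask(1)].any()
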