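"""Two-pass region growing: flood semantics, Otsu refinement,
parenchyma extraction and the orchestrated pipeline."""

import logging

import numpy as np
import pytest
from scipy import ndimage as ndi

from ichseg import (DegenerateHistogramError, GrowthCriterion,
                    NormalizedVolume, SeedPoint, ValidationError,
                    apply_window, extract_parenchyma, first_pass, grow,
                    mask_volume_ml, otsu_threshold, second_pass,
                    segment_hemorrhage, similarity, confusion)
from ichseg.phantom import PhantomSpec, make_phantom

from conftest import bfs_flood, otsu_exhaustive

# the worked 5x5 grid: seed (2,2), tau 0.30, 4-connectivity grows a
# 13-pixel diamond (the nine >=0.6 pixels plus the four 0.5 tips)
GRID_5X5 = np.array([
    [.1, .1, .5, .1, .1],
    [.1, .6, .7, .6, .1],
    [.5, .7, .8, .7, .5],
    [.1, .6, .7, .6, .1],
    [.1, .1, .5, .1, .1],
])


class TestGrow:
    def test_uniform_slice_floods_everything(self):
        img = np.full((3, 3), 0.5)
        mask = grow(img, [(1, 1)], GrowthCriterion(tau=0.1))
        assert mask.sum() == 9

    def test_tau_zero_unique_seed_intensity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 0.9, (8, 8))
        img[4, 4] = 0.95  # unique intensity
        mask = grow(img, [(4, 4)], GrowthCriterion(tau=0.0))
        assert mask.sum() == 1 and mask[4, 4]

    def test_printed_grid_diamond(self):
        mask = grow(GRID_5X5, [(2, 2)], GrowthCriterion(tau=0.30, connectivity=4))
        assert mask.sum() == 13
        np.testing.assert_array_equal(mask, bfs_flood(GRID_5X5, [(2, 2)], 0.30, 4))

    def test_matches_bruteforce_flood_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            img = rng.uniform(0, 1, (16, 16))
            tau = float(rng.uniform(0, 1))
            conn = int(rng.choice([4, 8]))
            seeds = [tuple(rng.integers(0, 16, 2)) for _ in range(rng.integers(1, 4))]
            got = grow(img, seeds, GrowthCriterion(tau=tau, connectivity=conn))
            np.testing.assert_array_equal(got, bfs_flood(img, seeds, tau, conn))

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (16, 16))
        seed = (8, 8)
        prev = None
        for tau in (0.05, 0.15, 0.35, 0.7, 1.0):
            mask = grow(img, [seed], GrowthCriterion(tau=tau))
            if prev is not None:
                assert np.all(prev <= mask)  # nested masks
            prev = mask

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 1, (20, 20))
        a = grow(img, [(3, 3), (15, 12)], GrowthCriterion(tau=0.4))
        b = grow(img, [(15, 12), (3, 3)], GrowthCriterion(tau=0.4))
        np.testing.assert_array_equal(a, b)

    def test_seed_outside_domain_rejected(self):
        img = np.zeros((4, 4))
        domain = np.zeros((4, 4), bool)
        with pytest.raises(ValidationError):
            grow(img, [(1, 1)], GrowthCriterion(), domain_mask=domain)


class TestFirstPass:
    def test_phantom_first_pass_covers_lesion(self, noisy_phantom):
        from ichseg import extract_seed_candidates, select_seeds

        norm = apply_window(noisy_phantom.ct)
        truth = noisy_phantom.truth.astype_bool()
        cands, labels = extract_seed_candidates(norm, return_labels=True)
        seeds = select_seeds(cands, mode="auto", k=1, volume=norm, labels=labels)
        res = first_pass(norm, seeds)
        dilated = ndi.binary_dilation(truth, iterations=2)
        got = res.mask.astype_bool()
        assert np.all(got <= dilated)  # strictly inside dilated truth
        s = similarity(confusion(res.mask, noisy_phantom.truth))
        assert s.dsi > 0.7

    def test_tau_one_floods_whole_slice(self):
        rng = np.random.default_rng(9)
        vol = NormalizedVolume(rng.uniform(0.2, 0.8, (1, 12, 12)),
                               spacing=(7.2, 1, 1))
        res = first_pass(vol, [SeedPoint((0, 6, 6))], tau=1.0)
        assert res.mask.voxel_count == 12 * 12

    def test_single_slice_lesion_stays_on_slice(self):
        ph = make_phantom(PhantomSpec(noise_sigma=0.0, rng_seed=17,
                                      semi_axes_mm=(3.0, 10.0, 10.0)))
        truth = ph.truth.astype_bool()
        assert truth.sum(axis=(1, 2)).astype(bool).sum() == 1
        norm = apply_window(ph.ct)
        z, r, c = (int(x[0]) for x in np.nonzero(truth))
        res = first_pass(norm, [SeedPoint((z, r, c))])
        nz = np.nonzero(res.per_slice_px)[0]
        assert list(nz) == [z]


class TestOtsu:
    def test_two_point_histogram_closed_form(self):
        values = np.array([0.2] * 50 + [0.8] * 50)
        t = otsu_threshold(values)
        assert 0.2 < t <= 0.8
        lo, hi = values[values < t], values[values >= t]
        sigma = (lo.size / 100) * (hi.size / 100) * (lo.mean() - hi.mean()) ** 2
        assert sigma == pytest.approx(0.25 * 0.6 ** 2)

    def test_four_value_sample(self):
        values = np.array([0.1, 0.1, 0.1, 0.9])
        t = otsu_threshold(values)
        assert 0.1 < t <= 0.9
        _, best_s = otsu_exhaustive(values)
        assert best_s == pytest.approx((3 / 4) * (1 / 4) * 0.8 ** 2)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full(10, 0.3))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            values = np.concatenate([
                rng.normal(0.3, 0.05, rng.integers(20, 80)),
                rng.normal(0.7, 0.05, rng.integers(20, 80)),
            ]).clip(0, 1)
            t_ref, _ = otsu_exhaustive(values)
            assert otsu_threshold(values) == pytest.approx(t_ref)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(24)
        values = rng.uniform(0.1, 0.5, 200)
        shift = 0.3
        assert otsu_threshold(values + shift) == \
            pytest.approx(otsu_threshold(values) + shift, abs=1e-12)


class TestSecondPass:
    def test_noiseless_phantom_exact(self, noiseless_phantom):
        norm = apply_window(noiseless_phantom.ct)
        truth = noiseless_phantom.truth.astype_bool()
        zs, rs, cs = np.nonzero(truth)
        seed = SeedPoint((int(zs[0]), int(rs[0]), int(cs[0])))
        res = second_pass(norm, first_pass(norm, [seed]))
        np.testing.assert_array_equal(res.mask.voxels,
                                      noiseless_phantom.truth.voxels)
        t = res.per_slice_threshold[int(zs[0])]
        assert 0.35 < t <= 0.70  # Otsu lands between parenchyma and blood

    def test_fixed_point_when_first_pass_complete(self, noiseless_phantom):
        norm = apply_window(noiseless_phantom.ct)
        truth = noiseless_phantom.truth.astype_bool()
        zs, rs, cs = np.nonzero(truth)
        seed = SeedPoint((int(zs[0]), int(rs[0]), int(cs[0])))
        first = first_pass(norm, [seed])
        # noiseless: pass 1 already recovers the full hyperdense component
        np.testing.assert_array_equal(first.mask.voxels,
                                      noiseless_phantom.truth.voxels)
        second = second_pass(norm, first)
        np.testing.assert_array_equal(second.mask.voxels, first.mask.voxels)

    def test_degenerate_roi_falls_back_with_warning(self, caplog):
        vol = NormalizedVolume(np.full((1, 10, 10), 0.5), spacing=(7.2, 1, 1))
        first = first_pass(vol, [SeedPoint((0, 5, 5))], tau=0.2)
        with caplog.at_level(logging.WARNING, logger="ichseg"):
            second = second_pass(vol, first)
        np.testing.assert_array_equal(second.mask.voxels, first.mask.voxels)
        assert any("degenerate" in r.message for r in caplog.records)


class TestExtractParenchyma:
    def test_phantom_interior_disc(self, noiseless_phantom):
        norm = apply_window(noiseless_phantom.ct)
        mask = extract_parenchyma(norm).astype_bool()
        values = norm.values
        assert not (values[mask] >= 0.999).any()   # no bone
        assert not (values[mask] <= 0.01).any()    # no exterior air
        # every brain/blood voxel is recovered
        tissue = (values > 0.01) & (values < 0.999)
        assert np.array_equal(mask, tissue)

    def test_toy_ring(self):
        img = np.zeros((7, 7))
        img[1:6, 1:6] = 1.0   # skull ring
        img[2:5, 2:5] = 0.4   # interior parenchyma
        vol = NormalizedVolume(img[None], spacing=(7.2, 1, 1))
        mask = extract_parenchyma(vol, SeedPoint((0, 3, 3))).astype_bool()
        assert mask.sum() == 9
        assert mask[0, 2:5, 2:5].all()

    def test_seed_on_bone_rejected(self):
        img = np.zeros((7, 7))
        img[1:6, 1:6] = 1.0
        img[2:5, 2:5] = 0.4
        vol = NormalizedVolume(img[None], spacing=(7.2, 1, 1))
        with pytest.raises(ValidationError, match="bone"):
            extract_parenchyma(vol, SeedPoint((0, 1, 1)))


class TestSegmentHemorrhage:
    def test_volume_close_to_truth(self, noisy_phantom):
        res, report = segment_hemorrhage(noisy_phantom.ct)
        dev = report["volume_ml"] - noisy_phantom.true_volume_ml["voxel"]
        assert abs(dev) <= 1.16
        assert report["volume_ml"] == pytest.approx(mask_volume_ml(res.mask))

    def test_skull_adjacent_mask_avoids_bone(self):
        ph = make_phantom(PhantomSpec(skull_adjacent=True, rng_seed=31))
        res, report = segment_hemorrhage(ph.ct)
        norm = apply_window(ph.ct)
        assert not (norm.values[res.mask.astype_bool()] >= 0.999).any()
        assert report["parenchyma_domain"]
        s = similarity(confusion(res.mask, ph.truth))
        assert s.dsi > 0.9

    def test_multifocal_two_components(self):
        ph = make_phantom(PhantomSpec(count=2, rng_seed=32))
        res, _ = segment_hemorrhage(ph.ct)
        _, n = ndi.label(res.mask.voxels, structure=np.ones((3, 3, 3)))
        assert n == 2
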