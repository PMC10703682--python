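"""Contamination masking, size-based picking, sphere detection, cleaning."""

import numpy as np
import pytest

from spcet.picking import (
    clean_particles,
    contamination_mask,
    detect_spheres,
    pick_size_based,
    sample_surface,
)
from spcet.simulator import make_shell_volume, simulate_picking_tomogram


class TestContaminationMask:
    def test_all_zero_volume_empty_mask(self):
        assert not contamination_mask(np.zeros((48, 48, 24))).any()

    def test_pure_noise_masked_fraction_tiny(self):
        fracs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            vol = rng.normal(size=(64, 64, 32))
            fracs.append(contamination_mask(vol, dilation_radius=2).mean())
        assert np.mean(fracs) < 0.01

    def test_dense_sphere_covered_with_shell(self):
        vol = np.zeros((64, 64, 64))
        z, y, x = np.meshgrid(*(np.arange(64),) * 3, indexing="ij")
        r = np.sqrt((x - 32.0) ** 2 + (y - 32.0) ** 2 + (z - 32.0) ** 2)
        vol[r <= 10] = -50.0
        mask = contamination_mask(vol, dilation_radius=5)
        assert mask[r <= 10].all()  # sphere covered
        assert mask[(r > 10) & (r <= 13)].all()  # dilation shell (within radius 5)


class TestSizeBasedPicking:
    def test_clean_spheres_all_found(self):
        vol, centers, _ = simulate_picking_tomogram(
            n_particles=20, snr=1e6, n_contamination=0, rng_seed=1
        )
        picks = pick_size_based(vol, 5.0, 1.0)
        assert len(picks) == 20
        for c in centers:
            d = np.linalg.norm(picks.positions - c, axis=1).min()
            assert d <= 2.0

    def test_pick_inside_contamination_excluded(self):
        vol, centers, _ = simulate_picking_tomogram(
            n_particles=20, snr=1e6, n_contamination=0, rng_seed=1
        )
        # paint one particle as contamination-grade density
        target = centers[0]
        z, y, x = np.meshgrid(*(np.arange(s) for s in vol.shape), indexing="ij")
        r = np.sqrt((x - target[0]) ** 2 + (y - target[1]) ** 2 + (z - target[2]) ** 2)
        vol2 = vol.copy()
        vol2[r < 9] = -60.0
        mask = contamination_mask(vol2, dilation_radius=3)
        picks = pick_size_based(vol2, 5.0, 1.0, mask)
        assert len(picks) == 19
        assert np.linalg.norm(picks.positions - target, axis=1).min() > 5.0

    def test_empty_tomogram_zero_picks(self):
        rng = np.random.default_rng(0)
        picks = pick_size_based(rng.normal(size=(48, 48, 24)), 5.0, 1.0)
        assert len(picks) == 0 or len(picks) < 3  # no guaranteed peaks in noise

    def test_radius_guard(self):
        with pytest.raises(ValueError):
            pick_size_based(np.zeros((32, 32, 16)), 2.0, 2.0)


class TestDetectSpheres:
    def test_single_shell(self):
        vol = -make_shell_volume((80, 80, 80), [(40, 40, 40)], [30])
        centers, radii, _ = detect_spheres(vol, (20, 40), radius_step=2)
        assert len(centers) == 1
        assert np.linalg.norm(centers[0] - (40, 40, 40)) <= 2.0
        assert abs(radii[0] - 30) <= 2.0

    def test_two_shells_radius_ordering(self):
        vol = -make_shell_volume(
            (128, 96, 96), [(32, 48, 48), (96, 48, 48)], [25, 35]
        )
        centers, radii, _ = detect_spheres(vol, (20, 40), radius_step=2.5)
        assert len(centers) == 2
        order = np.argsort(centers[:, 0])
        assert radii[order[0]] < radii[order[1]]

    def test_noise_only_no_detections(self):
        hits = 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            vol = rng.normal(size=(64, 64, 64))
            centers, _, _ = detect_spheres(vol, (15, 25), radius_step=5)
            hits += len(centers) > 0
        assert hits == 0


class TestSampleSurface:
    def test_count_matches_area(self):
        ps = sample_surface((0, 0, 0), 30.0, spacing_A=10.0, pixel_size=1.0)
        expected = 4 * np.pi * 30.0**2 / 10.0**2
        assert abs(len(ps) - expected) / expected < 0.1

    def test_normals_unit_and_outward(self):
        ps = sample_surface((5, 5, 5), 20.0, 8.0)
        assert np.allclose(np.linalg.norm(ps.normals, axis=1), 1.0, atol=1e-6)
        rel = ps.positions - np.array([5.0, 5.0, 5.0])
        assert np.all(np.einsum("ij,ij->i", ps.normals, rel) > 0)

    def test_hemispheric_spacing_few_points(self):
        r = 12.0
        ps = sample_surface((0, 0, 0), r, spacing_A=np.pi * r, pixel_size=1.0)
        assert len(ps) <= 4


class TestCleanParticles:
    def test_bimodal_auto_threshold(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.1, 0.02, 50)
        hi = rng.normal(0.5, 0.02, 50)
        scores = np.concatenate([lo, hi])
        pos = rng.uniform(0, 100, (100, 3))
        kept = clean_particles(pos, scores, "auto", min_distance=0.0)
        assert set(kept) == set(range(50, 100))

    def test_unimodal_warns_and_keeps_all(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0.3, 0.05, 80)
        pos = rng.uniform(0, 100, (80, 3))
        with pytest.warns(UserWarning, match="bimodal"):
            kept = clean_particles(pos, scores, "auto", min_distance=0.0)
        assert len(kept) == 80

    def test_zero_min_distance_no_dedup(self):
        pos = np.array([[0, 0, 0], [0.5, 0, 0]])
        kept = clean_particles(pos, [1.0, 0.9], None, min_distance=0.0)
        assert len(kept) == 2

    def test_close_pair_keeps_higher_score(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [50, 50, 50]])
        kept = clean_particles(pos, [0.2, 0.9, 0.5], None, min_distance=10.0)
        assert list(kept) == [1, 2]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 60, (40, 3))
        scores = rng.uniform(0, 1, 40)
        k1 = clean_particles(pos, scores, None, min_distance=15.0)
        k2 = clean_particles(pos[k1], scores[k1], None, min_distance=15.0)
        assert np.array_equal(k2, np.arange(len(k1)))

    def test_projection_scores_averaged(self):
        scores = np.array([[0.2, 0.4, np.nan], [0.8, 0.6, 0.7]])
        pos = np.array([[0, 0, 0], [30, 30, 30]])
        kept = clean_particles(pos, scores, 0.5, min_distance=0.0)
        assert list(kept) == [1]
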