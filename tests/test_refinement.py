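"""Projection-matching score and the constrained refiners."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spcet.geometry import ParticlePose, RegionGrid, euler_to_matrix, matrix_to_euler
from spcet.projector import FourierProjector, band_mask
from spcet.refinement import (
    ScoreModel,
    SearchLimits,
    global_search,
    refine_fully_constrained,
    refine_region_geometry,
    refine_tilt_geometry,
    score_projection,
)
from spcet.simulator import SimulationSpec, simulate_tilt_series
from spcet.stack import extract_crops


def angular_error(a: ParticlePose, b: ParticlePose) -> float:
    c = (np.trace(euler_to_matrix(a.angles).T @ euler_to_matrix(b.angles)) - 1) / 2
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def perturb(particles, angle_deg, shift_vox, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for p in particles:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix() @ euler_to_matrix(p.angles)
        dp = rng.normal(size=3)
        dp *= shift_vox / np.linalg.norm(dp)
        out.append(ParticlePose(p.particle_id, p.pos + dp, matrix_to_euler(R)))
    return out


class TestScoreProjection:
    def test_self_match_noiseless(self, noiseless_ds, noiseless_model):
        table, agg = noiseless_model.score_table(noiseless_ds.particles)
        assert np.nanmin(table) > 0.999

    def test_pure_noise_null(self):
        rng = np.random.default_rng(0)
        n, px = 32, 2.0
        vol = rng.normal(size=(n, n, n))
        pr = FourierProjector(np.abs(vol))
        mask = band_mask(n, px, (100.0, 6.0))
        m = int(mask.sum())
        hits = 0
        trials = 40
        for i in range(trials):
            img = rng.normal(size=(n, n))
            d = score_projection(img, pr, (0.0, 0.0, 0.0), None, (100.0, 6.0), px)
            if abs(d) < 3.0 / np.sqrt(m):
                hits += 1
        assert hits / trials >= 0.9

    def test_shift_theorem(self, noiseless_ds, noiseless_model):
        """Shifting the image and correcting the pose shift leaves d unchanged."""
        ds, model = noiseless_ds, noiseless_model
        p = 0
        part = ds.particles[p]
        d0, _ = model.particle_scores(p, part.angles, part.pos)
        shifted = ParticlePose(p, part.pos + np.array([2.0, -1.0, 0.0]), part.angles)
        d1, _ = model.particle_scores(p, shifted.angles, shifted.pos)
        moved_back = ParticlePose(p, part.pos, part.angles)
        d2, _ = model.particle_scores(p, moved_back.angles, moved_back.pos)
        assert np.allclose(d0, d2, atol=1e-12)
        assert d1.mean() < d0.mean() - 1e-3  # wrong shift costs score


class TestFullyConstrained:
    def test_zero_perturbation_fixed_point(self, noiseless_ds, noiseless_model):
        refined, info = refine_fully_constrained(
            noiseless_model, noiseless_ds.particles, SearchLimits(angle=2.0, shift=1.0)
        )
        for t, r in zip(noiseless_ds.particles, refined):
            assert angular_error(t, r) < 0.2
            assert np.linalg.norm(t.pos - r.pos) < 0.2

    def test_zero_limits_identity(self, small_ds, small_model):
        refined, _ = refine_fully_constrained(
            small_model, small_ds.particles, SearchLimits(angle=0.0, shift=0.0, z=0.0)
        )
        for t, r in zip(small_ds.particles, refined):
            assert t.angles == r.angles
            assert np.array_equal(t.pos, r.pos)

    def test_monotone_score_gain(self, small_ds, small_model):
        pert = perturb(small_ds.particles, 4.0, 2.0, seed=3)
        refined, info = refine_fully_constrained(
            small_model, pert, SearchLimits(angle=6.0, shift=3.0)
        )
        assert np.all(info["score_gain"] >= -1e-9)

    def test_recovery_small_scale(self, small_ds, small_model):
        pert = perturb(small_ds.particles, 5.0, 3.0, seed=4)
        refined, _ = refine_fully_constrained(
            small_model, pert, SearchLimits(angle=8.0, shift=5.0)
        )
        errs = [angular_error(t, r) for t, r in zip(small_ds.particles, refined)]
        pos = [np.linalg.norm(t.pos - r.pos) for t, r in zip(small_ds.particles, refined)]
        init = [angular_error(t, r) for t, r in zip(small_ds.particles, pert)]
        assert np.median(errs) < 0.5 * np.median(init)
        assert np.median(pos) < 0.5


class TestRegionGeometry:
    def test_single_region_equals_global(self, small_ds, small_model):
        grid = RegionGrid(1, 1, 1, small_ds.spec.tomogram_dims)
        d_region, _ = refine_region_geometry(
            small_model, small_ds.particles, grid,
            SearchLimits(angle=0.0, shift=2.0), min_particles=1,
        )
        d_global, _ = refine_tilt_geometry(
            small_model, small_ds.particles, SearchLimits(angle=0.0, shift=2.0)
        )
        assert np.allclose(d_region[0], d_global)

    def test_sparse_region_warns_and_keeps_zero(self, small_ds, small_model):
        grid = RegionGrid(8, 8, 2, small_ds.spec.tomogram_dims)
        with pytest.warns(UserWarning):
            deltas, info = refine_region_geometry(
                small_model, small_ds.particles, grid,
                SearchLimits(angle=0.0, shift=2.0), min_particles=5,
            )
        for g in info["skipped_regions"]:
            assert np.allclose(deltas[g], 0.0)
        assert len(info["skipped_regions"]) > 0


class TestGlobalSearch:
    def test_grid_coincident_truth_recovered(self):
        """Noiseless particles with orientations on the search grid are found exactly."""
        spec = SimulationSpec(n_particles=3, betas=np.arange(-40, 40.1, 10.0), snr=1e9, rng_seed=55)
        base = simulate_tilt_series(spec)
        snapped = [
            ParticlePose(p.particle_id, p.pos, (round(p.angles[0] / 45) * 45,
                                                min(135, max(45, round(p.angles[1] / 45) * 45)),
                                                round(p.angles[2] / 45) * 45))
            for p in base.particles
        ]
        ds = simulate_tilt_series(spec, particles=snapped)
        stack = extract_crops(ds.tilt_images, ds.tilts, snapped, spec.box, spec.tomogram_dims, spec.pixel_size)
        model = ScoreModel(ds.phantom, stack, band=(100.0, 6.0), tilt_ctfs=ds.tilt_ctfs)
        poses, _ = global_search(model, [p.pos for p in snapped], angular_step=45.0, shift_range=1.0)
        for t, r in zip(snapped, poses):
            assert angular_error(t, r) < 1e-6
            assert np.allclose(t.pos, r.pos)

    def test_normal_prior_fewer_evaluations(self, small_ds):
        spec = small_ds.spec
        stack = extract_crops(
            small_ds.tilt_images, small_ds.tilts, small_ds.particles,
            spec.box, spec.tomogram_dims, spec.pixel_size,
        )
        model = ScoreModel(small_ds.phantom, stack, band=(100.0, 8.0),
                           tilt_ctfs=small_ds.tilt_ctfs, binning=2)
        sub = [small_ds.particles[i] for i in range(3)]
        priors = [euler_to_matrix(p.angles) @ np.array([0.0, 0.0, 1.0]) for p in sub]
        _, n_full = global_search(model, [p.pos for p in sub], angular_step=30.0, shift_range=1.0)
        poses, n_prior = global_search(
            model, [p.pos for p in sub], angular_step=30.0, shift_range=1.0,
            normal_priors=priors,
        )
        assert n_full >= 10 * n_prior
        for t, r in zip(sub, poses):
            assert angular_error(t, r) < 45.0  # within grid spacing of truth

    def test_step_below_one_rejected(self, small_model):
        with pytest.raises(ValueError):
            global_search(small_model, [(0, 0, 0)], angular_step=0.5)
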