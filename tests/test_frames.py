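"""Running averages, trajectory refinement and regularization behavior."""

import numpy as np
import pytest

from spcet.frames import refine_trajectories, running_averages
from spcet.refinement import ScoreModel
from spcet.simulator import FrameModel, SimulationSpec, simulate_tilt_series
from spcet.stack import extract_crops


def frames_dataset(**kw):
    fm_kw = dict(n_frames=6, drift_sigma=0.05, drift_linear=0.2)
    fm_kw.update(kw.pop("frame_kw", {}))
    defaults = dict(
        n_particles=8,
        betas=np.arange(-30.0, 30.1, 10.0),
        snr=0.5,
        rng_seed=77,
        frames=FrameModel(**fm_kw),
    )
    defaults.update(kw)
    spec = SimulationSpec(**defaults)
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    model = ScoreModel(ds.phantom, stack, band=(100.0, 6.0), tilt_ctfs=ds.tilt_ctfs)
    return ds, model


class TestRunningAverages:
    def test_window_one_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(6, 16, 16))
        assert np.array_equal(running_averages(frames, 1), frames)

    def test_full_window_global_average(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(5, 8, 8))
        out = running_averages(frames, 5)
        full = frames.mean(axis=0)
        for f in range(5):
            assert np.allclose(out[f], full)

    def test_interior_variance_reduction(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(64, 24, 24))
        w = 4
        out = running_averages(frames, w)
        interior = out[w : 64 - w]
        ratio = interior.var() / frames.var()
        assert abs(ratio - 1.0 / w) < 0.1 / w * 4  # within ~10%

    def test_window_bounds(self):
        with pytest.raises(ValueError):
            running_averages(np.zeros((4, 8, 8)), 5)


class TestRefineTrajectories:
    def test_linear_drift_recovered(self):
        ds, model = frames_dataset()
        trajs, _ = refine_trajectories(model, ds.frames, ds.particles, lambda_t=2.0, lambda_s=1.0)
        f = np.arange(ds.spec.frames.n_frames)
        errs = []
        for t in range(len(ds.tilts)):
            true_slope = np.polyfit(f, ds.frame_trajectories[t], 1)[0]
            rec = np.mean([tr.shifts for tr in trajs if tr.tilt_index == t], axis=0)
            rec_slope = np.polyfit(f, rec, 1)[0]
            errs.append(np.linalg.norm(true_slope - rec_slope))
        assert np.mean(errs) < 0.05

    def test_zero_drift_high_snr_null(self):
        ds, model = frames_dataset(
            frame_kw=dict(drift_sigma=0.0, drift_linear=0.0), snr=20.0, rng_seed=78
        )
        trajs, _ = refine_trajectories(model, ds.frames, ds.particles)
        worst = max(np.abs(tr.shifts).max() for tr in trajs)
        assert worst < 0.2

    def test_strong_temporal_penalty_linearizes(self):
        ds, model = frames_dataset()
        trajs, _ = refine_trajectories(
            model, ds.frames, ds.particles, lambda_t=1e8, lambda_s=0.0
        )
        for tr in trajs[:10]:
            second = np.diff(tr.shifts, n=2, axis=0)
            assert np.abs(second).max() < 1e-3

    def test_regularization_reduces_second_differences(self):
        ds, model = frames_dataset(rng_seed=79)
        raw_trajs, _ = refine_trajectories(
            model, ds.frames, ds.particles, lambda_t=0.0, lambda_s=0.0
        )
        reg_trajs, _ = refine_trajectories(
            model, ds.frames, ds.particles, lambda_t=5.0, lambda_s=2.0
        )
        raw_norm = np.mean([
            np.linalg.norm(np.diff(tr.shifts, n=2, axis=0)) for tr in raw_trajs
        ])
        reg_norm = np.mean([
            np.linalg.norm(np.diff(tr.shifts, n=2, axis=0)) for tr in reg_trajs
        ])
        assert reg_norm <= raw_norm + 1e-12

    def test_single_frame_zero_trajectory(self):
        ds, model = frames_dataset()
        trajs, _ = refine_trajectories(model, ds.frames[:, :1], ds.particles)
        assert all(np.allclose(tr.shifts, 0.0) for tr in trajs)


def test_bell_shaped_frame_scores():
    """With early-frame motion blur and late-frame damage the per-frame mean
    score rises then falls within a tilt, and decreases across tilts."""
    ds, model = frames_dataset(
        frame_kw=dict(
            n_frames=8,
            drift_sigma=0.05,
            drift_linear=0.05,
            settle_drift=3.0,
            settle_tau=1.5,
            intra_frame_blur=4.0,
            intra_frame_damage=25.0,
        ),
        n_particles=12,
        snr=2.0,
        rng_seed=80,
    )
    trajs, fscores = refine_trajectories(model, ds.frames, ds.particles)
    mean_curve = fscores.mean(axis=0)
    peak = int(np.argmax(mean_curve))
    assert 0 < peak < len(mean_curve) - 1  # interior maximum: bell shape
    assert mean_curve[0] < mean_curve[peak]
    assert mean_curve[-1] < mean_curve[peak]
    # across tilts: later exposures score lower on average
    order = np.array([t.exposure_order for t in ds.tilts])
    per_tilt = fscores.mean(axis=1)
    first_half = per_tilt[order < len(order) // 2].mean()
    second_half = per_tilt[order >= len(order) // 2].mean()
    assert second_half < first_half
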