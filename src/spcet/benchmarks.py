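"""Standard synthetic benchmarks with known ground truth.

Each function simulates a dataset under the standard study conditions, runs
the corresponding part of the pipeline, and returns the measured recovery
metrics.  The problem sizes are chosen so a single benchmark completes in
minutes on one CPU; the conditions (tilt scheme, SNR, perturbation sizes,
injected errors) are fixed properties of the benchmarks, not tuning knobs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .classification import classify_constrained, classify_unconstrained, match_class_labels
from .ctf import CTFParams, refine_region_ctf
from .frames import align_and_weight_frames, refine_trajectories
from .geometry import ParticlePose, RegionGrid, euler_to_matrix, matrix_to_euler
from .picking import contamination_mask, pick_size_based
from .reconstruction import (
    exposure_weights,
    fsc,
    fsc_resolution,
    merge_bundles,
    normalize_map,
    reconstruct,
)
from .refinement import (
    ScoreModel,
    SearchLimits,
    refine_fully_constrained,
    refine_region_geometry,
    refine_tilt_geometry,
)
from .simulator import (
    DeformationModel,
    FrameModel,
    SimulationSpec,
    benchmark_spec,
    simulate_picking_tomogram,
    simulate_tilt_series,
)
from .stack import extract_crops

__all__ = [
    "pose_recovery_benchmark",
    "deformation_recovery_benchmark",
    "ctf_recovery_benchmark",
    "classification_benchmark",
    "frame_benchmark",
    "picking_benchmark",
    "oracle_benchmark",
]


def _angular_error(a: ParticlePose, b: ParticlePose) -> float:
    c = (np.trace(euler_to_matrix(a.angles).T @ euler_to_matrix(b.angles)) - 1) / 2
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def _perturb(particles, angle_deg, shift_vox, rng):
    out = []
    for p in particles:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix() @ euler_to_matrix(
            p.angles
        )
        dp = rng.normal(size=3)
        dp *= shift_vox / np.linalg.norm(dp)
        out.append(ParticlePose(p.particle_id, p.pos + dp, matrix_to_euler(R)))
    return out


def pose_recovery_benchmark(seed: int = 42) -> dict:
    """Fully constrained refinement from 5 deg / 3 voxel perturbed poses.

    Standard benchmark: 64-voxel box, 41 tilts -60..60 step 3, SNR 0.5,
    50 particles; refinement at 2x binning.
    """
    spec = benchmark_spec(rng_seed=seed)
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    model = ScoreModel(ds.phantom, stack, band=(100.0, 9.0), tilt_ctfs=ds.tilt_ctfs, binning=2)
    rng = np.random.default_rng(seed + 1)
    perturbed = _perturb(ds.particles, 5.0, 3.0, rng)
    refined, _ = refine_fully_constrained(model, perturbed, SearchLimits(angle=8.0, shift=5.0))
    ang = [_angular_error(t, r) for t, r in zip(ds.particles, refined)]
    shift = [np.linalg.norm(t.pos - r.pos) for t, r in zip(ds.particles, refined)]
    ang0 = [_angular_error(t, r) for t, r in zip(ds.particles, perturbed)]
    return {
        "initial_median_angular_error_deg": float(np.median(ang0)),
        "median_angular_error_deg": float(np.median(ang)),
        "median_shift_error_vox": float(np.median(shift)),
        "n": len(refined),
    }


def deformation_recovery_benchmark(seed: int = 17) -> dict:
    """Region-based refinement of an injected per-region shift field (max 4 px).

    Compares the half-map FSC resolution of reconstructions using the
    recovered per-region corrections against global-only (single-region)
    corrections.
    """
    spec = benchmark_spec(deformation=DeformationModel(grid=(2, 2, 1), max_shift=4.0), rng_seed=seed)
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    model = ScoreModel(ds.phantom, stack, band=(100.0, 9.0), tilt_ctfs=ds.tilt_ctfs, binning=2)
    grid = RegionGrid(2, 2, 1, spec.tomogram_dims)
    deltas, info = refine_region_geometry(
        model, ds.particles, grid, SearchLimits(angle=0.0, shift=6.0), min_particles=5
    )
    pops = np.bincount(info["region_ids"], minlength=grid.n_regions)
    ok = pops >= 10
    err = deltas[ok][:, :, 2:4] - ds.true_deltas[ok][:, :, 2:4]
    rms = float(np.sqrt((err**2).mean()))

    global_deltas, _ = refine_tilt_geometry(
        model, ds.particles, SearchLimits(angle=0.0, shift=6.0)
    )
    region_ids = info["region_ids"]
    _, h0r, h1r, _ = reconstruct(
        stack, ds.particles, ds.tilt_ctfs, region_deltas=deltas, region_ids=region_ids
    )
    g_all = np.broadcast_to(global_deltas, (grid.n_regions,) + global_deltas.shape)
    _, h0g, h1g, _ = reconstruct(
        stack, ds.particles, ds.tilt_ctfs, region_deltas=g_all, region_ids=region_ids
    )
    res_region = fsc_resolution(*fsc(h0r, h1r, spec.pixel_size))
    res_global = fsc_resolution(*fsc(h0g, h1g, spec.pixel_size))
    return {
        "shift_rms_error_px": rms,
        "fsc_resolution_region_A": float(res_region),
        "fsc_resolution_global_A": float(res_global),
        "n": int(ok.sum() * len(ds.tilts)),
    }


def ctf_recovery_benchmark(seed: int = 9, injected: float = 1000.0) -> dict:
    """Recovery of an injected regional defocus error by CTF refinement."""
    spec = SimulationSpec(
        n_particles=15, betas=np.arange(-60.0, 60.1, 3.0), snr=0.5, rng_seed=seed
    )
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    wrong = [
        CTFParams(c.df1 + injected, c.df2 + injected, c.astig_angle, c.voltage, c.cs, c.amplitude_contrast)
        for c in ds.tilt_ctfs
    ]
    model = ScoreModel(ds.phantom, stack, band=(100.0, 5.0), tilt_ctfs=wrong)
    region_ids = np.zeros(len(ds.particles), dtype=int)
    result, _ = refine_region_ctf(model, ds.particles, region_ids, wrong, tolerance=2000.0)
    recovered = 0.5 * (result[0].df1 + result[0].df2)
    return {
        "injected_error_A": injected,
        "recovered_offset_A": float(recovered),
        "residual_error_A": float(abs(recovered + injected)),
        "n": len(ds.particles),
    }


def classification_benchmark(seed: int = 21, n_particles: int = 200, n_iter: int = 30) -> dict:
    """Two-variant mixture at SNR 0.2: constrained vs per-projection EM."""
    spec = SimulationSpec(
        n_particles=n_particles,
        tomogram_dims=(768, 768, 48),
        betas=np.arange(-60.0, 60.1, 6.0),
        snr=0.2,
        two_variants=True,
        rng_seed=seed,
    )
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    model = ScoreModel(ds.phantom, stack, band=(100.0, 6.0), tilt_ctfs=ds.tilt_ctfs)
    cm = classify_constrained(model, ds.particles, 2, n_iter=n_iter, rng_seed=seed + 1)
    acc_c, _ = match_class_labels(cm.assignments, ds.class_labels, 2)

    occ_u, _, _ = classify_unconstrained(model, ds.particles, 2, n_iter=n_iter, rng_seed=seed + 1)
    votes = np.argmax(occ_u, axis=2)
    accs = []
    for perm in ((0, 1), (1, 0)):
        mapped = np.asarray(perm)[votes]
        accs.append(float((mapped == ds.class_labels[:, None]).mean()))
    acc_u = max(accs)
    return {
        "constrained_accuracy": float(acc_c),
        "unconstrained_accuracy": float(acc_u),
        "constrained_misassigned": int(round((1 - acc_c) * n_particles)),
        "unconstrained_misassigned_fraction": float(1 - acc_u),
        "iterations": cm.iteration,
        "n": n_particles,
    }


def frame_benchmark(seed: int = 77) -> dict:
    """Linear-drift recovery plus exposure-weighted vs unweighted reconstruction.

    Two scenarios: (1) frames carrying 0.2 px/frame linear drift plus a small
    random walk — the trajectory refiner must recover the drift slope; (2) a
    dose-attenuated acquisition (early settle motion blur, late intra-frame
    radiation damage) on which score-driven exposure weighting is compared
    against a plain aligned frame average.
    """
    # scenario 1: drift recovery
    spec = SimulationSpec(
        n_particles=12,
        betas=np.arange(-48.0, 48.1, 8.0),
        snr=0.5,
        rng_seed=seed,
        frames=FrameModel(n_frames=8, drift_sigma=0.05, drift_linear=0.2),
    )
    ds = simulate_tilt_series(spec)
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    model = ScoreModel(ds.phantom, stack, band=(100.0, 6.0), tilt_ctfs=ds.tilt_ctfs)
    trajs, _ = refine_trajectories(model, ds.frames, ds.particles)
    F = spec.frames.n_frames
    f = np.arange(F)
    slope_errs = []
    for t in range(len(ds.tilts)):
        true_slope = np.polyfit(f, ds.frame_trajectories[t], 1)[0]
        rec = np.mean([tr.shifts for tr in trajs if tr.tilt_index == t], axis=0)
        rec_slope = np.polyfit(f, rec, 1)[0]
        slope_errs.append(np.linalg.norm(true_slope - rec_slope))

    # scenario 2: damaged frames, exposure weighting
    spec2 = SimulationSpec(
        n_particles=12,
        betas=np.arange(-48.0, 48.1, 8.0),
        snr=0.5,
        rng_seed=seed + 1,
        frames=FrameModel(
            n_frames=8,
            drift_sigma=0.05,
            drift_linear=0.2,
            settle_drift=3.0,
            settle_tau=1.5,
            intra_frame_blur=4.0,
            intra_frame_damage=25.0,
        ),
    )
    ds2 = simulate_tilt_series(spec2)
    stack2 = extract_crops(
        ds2.tilt_images, ds2.tilts, ds2.particles, spec2.box, spec2.tomogram_dims, spec2.pixel_size
    )
    model2 = ScoreModel(ds2.phantom, stack2, band=(100.0, 6.0), tilt_ctfs=ds2.tilt_ctfs)
    trajs2, fscores2 = refine_trajectories(model2, ds2.frames, ds2.particles)

    from .projector import freq_grid_2d

    T = len(ds2.tilts)
    _, _, kabs, _ = freq_grid_2d(stack2.box, spec2.pixel_size)
    w_flat = exposure_weights(fscores2.reshape(-1), kabs)  # (T*F, n, n)
    w = w_flat.reshape(T, F, stack2.box, stack2.box)
    w = w / w.sum(axis=1, keepdims=True)  # renormalize within each tilt

    aligned_u = align_and_weight_frames(stack2, ds2.frames, trajs2, frame_weights=None)
    aligned_w = align_and_weight_frames(stack2, ds2.frames, trajs2, frame_weights=w)
    map_u, _, _, _ = reconstruct(aligned_u, ds2.particles, ds2.tilt_ctfs)
    map_w, _, _, _ = reconstruct(aligned_w, ds2.particles, ds2.tilt_ctfs)
    freqs, curve_u = fsc(map_u, ds2.phantom, spec2.pixel_size)
    _, curve_w = fsc(map_w, ds2.phantom, spec2.pixel_size)
    return {
        "drift_slope_error_px_per_frame": float(np.mean(slope_errs)),
        "weighted_fsc_resolution_A": float(fsc_resolution(freqs, curve_w)),
        "unweighted_fsc_resolution_A": float(fsc_resolution(freqs, curve_u)),
        "weighted_mean_fsc": float(np.mean(curve_w)),
        "unweighted_mean_fsc": float(np.mean(curve_u)),
        "n": len(trajs) + len(trajs2),
    }


def picking_benchmark(seed: int = 11) -> dict:
    """Size-based picking on the standard contaminated tomogram (30 particles,
    SNR 0.5, 2 contamination blobs); true positive = pick within one particle
    radius of a truth center."""
    radius = 5.0
    vol, centers, _ = simulate_picking_tomogram(
        n_particles=30, particle_radius=radius, snr=0.5, n_contamination=2, rng_seed=seed
    )
    mask = contamination_mask(vol, dilation_radius=5)
    picks = pick_size_based(vol, radius, 1.0, mask)
    tp = 0
    used: set[int] = set()
    for p in picks.positions:
        d = np.linalg.norm(centers - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= radius and j not in used:
            tp += 1
            used.add(j)
    precision = tp / len(picks) if len(picks) else 0.0
    recall = tp / len(centers)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"f1": float(f1), "precision": float(precision), "recall": float(recall), "n": int(len(centers))}


def oracle_benchmark(seed: int = 2, n_cases: int = 10_000) -> dict:
    """Exactness checks: pose composition vs a brute-force rotation-matrix
    oracle, and order-invariance of bundle merging."""
    from .geometry import TiltGeometry, compose_projection_pose
    from .reconstruction import PartialReconstruction

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        alpha, beta = rng.uniform(-180, 180), rng.uniform(-60, 60)
        ang = rng.uniform([-180, 1, -180], [180, 179, 180])
        pos = rng.uniform(-30, 30, 3)
        tilt = TiltGeometry(0, alpha, beta)
        pose = compose_projection_pose(tilt, ParticlePose(0, pos, ang))
        M = (
            Rotation.from_euler("z", alpha, degrees=True)
            * Rotation.from_euler("y", beta, degrees=True)
            * Rotation.from_euler("z", -alpha, degrees=True)
        ).as_matrix()
        Q = M @ Rotation.from_euler("ZYZ", ang, degrees=True).as_matrix()
        u = M @ pos
        worst = max(worst, float(np.abs(np.subtract(pose.shift, u[:2])).max()))
        worst = max(worst, float(np.abs(euler_to_matrix(pose.angles) - Q).max()))

    parts = []
    for _ in range(5):
        p = PartialReconstruction.empty(16)
        p.num += rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
        p.den += rng.uniform(size=(16, 16, 16))
        parts.append(p)
    ref = normalize_map(merge_bundles(parts))
    dev = 0.0
    for _ in range(4):
        order = rng.permutation(5)
        m = normalize_map(merge_bundles([parts[i] for i in order]))
        dev = max(dev, float(np.abs(m - ref).max()))
    return {"compose_max_error": worst, "merge_max_deviation": dev, "n": n_cases}
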