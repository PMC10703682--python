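"""Per-particle video-frame trajectory refinement and frame-level scores.

Beam-induced motion during a tilt exposure is estimated per particle and per
tilt from the raw video frames: running frame averages are aligned against
reprojections of the current 3D reference, giving one noisy trajectory per
(particle, tilt); the trajectories are then regularized with temporal
(second-difference) and spatial (neighboring-particle) smoothness penalties
solved in closed form.  Per-frame mean scores over all particles feed the
score-driven exposure weighting of the reconstruction module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .projector import centered_fft2
from .refinement import ScoreModel

__all__ = [
    "FrameTrajectory",
    "running_averages",
    "refine_trajectories",
    "align_and_weight_frames",
]


@dataclass
class FrameTrajectory:
    """Estimated per-frame 2D shifts (pixels, relative to frame 0) and scores."""

    particle_id: int
    tilt_index: int
    shifts: np.ndarray  # (F, 2)
    scores: np.ndarray  # (F,)


def running_averages(frames: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along the first axis with edge truncation.

    ``window = 1`` is the identity; ``window = n_frames`` makes every output
    the full average.  Output count equals input count.
    """
    frames = np.asarray(frames, dtype=float)
    F = frames.shape[0]
    if not 1 <= window <= F:
        raise ValueError(f"window must be in [1, {F}], got {window}")
    if window == 1:
        return frames.copy()
    csum = np.concatenate([np.zeros((1,) + frames.shape[1:]), np.cumsum(frames, axis=0)])
    half_lo = (window - 1) // 2
    out = np.empty_like(frames)
    for f in range(F):
        # centered window; at the edges the window slides inward so every
        # output averages exactly `window` frames
        lo = int(np.clip(f - half_lo, 0, F - window))
        hi = lo + window
        out[f] = (csum[hi] - csum[lo]) / window
    return out


def _second_difference_penalty(F: int) -> sparse.csr_matrix:
    if F < 3:
        return sparse.csr_matrix((F, F))
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(F - 2, F))
    return (D.T @ D).tocsr()


def refine_trajectories(
    model: ScoreModel,
    frame_stacks: np.ndarray,
    particles,
    lambda_t: float = 2.0,
    lambda_s: float = 1.0,
    neighbor_radius: float = 120.0,
    max_shift: int = 5,
    window: int | str = 1,
    score_floor: float = 0.05,
):
    """Refine per-(particle, tilt) frame trajectories against the reference.

    For every frame, the shift is the arg-max of the band-limited correlation
    between the (running-averaged) frame crop and the reference reprojection
    at the particle's pose, on a bounded integer grid with quadratic
    interpolation.  Raw trajectories are then smoothed by minimizing::

        sum ||raw - s||^2 + lambda_t * sum ||second time-differences of s||^2
                          + lambda_s * sum_{neighbor pairs} ||s_p - s_q||^2

    per tilt (neighbors = particles within ``neighbor_radius`` unbinned
    pixels in the projection).  ``window="auto"`` doubles the running-average
    window until the mean raw score reaches ``score_floor`` (low per-frame
    SNR protection).

    Parameters
    ----------
    model:
        Unbinned :class:`~spcet.refinement.ScoreModel` built on the tilt
        images the frames belong to.
    frame_stacks:
        (T, F, ny, nx) raw frames of each tilt.

    Returns
    -------
    (trajectories, frame_scores)
        ``trajectories``: list of :class:`FrameTrajectory`, one per valid
        (particle, tilt); ``frame_scores``: (T, F) mean raw score per frame.
    """
    if model.stack.binning != 1:
        raise ValueError("frame refinement runs on the unbinned stack")
    stack = model.stack
    T, F = frame_stacks.shape[:2]
    if F == 1:
        trajs = [
            FrameTrajectory(int(p), int(t), np.zeros((1, 2)), np.zeros(1))
            for p in range(stack.n_particles)
            for t in range(T)
            if stack.valid[p, t]
        ]
        return trajs, np.zeros((T, 1))
    nb = stack.box
    h = nb // 2
    ny, nx = frame_stacks.shape[2:]
    img_c = np.array([nx // 2, ny // 2])

    # integer shift grid and its phase ramps on the band points
    ax = np.arange(-max_shift, max_shift + 1, dtype=float)
    dyg, dxg = np.meshgrid(ax, ax, indexing="ij")
    dgrid = np.column_stack([dxg.ravel(), dyg.ravel()])  # (S, 2)
    S = dgrid.shape[0]
    side = 2 * max_shift + 1
    ph = np.exp(
        -2j * np.pi * (model.kx[None, :] * dgrid[:, 0, None] + model.ky[None, :] * dgrid[:, 1, None]) / nb
    )  # (S, m)

    trajectories: list[FrameTrajectory] = []
    sums = np.zeros((T, F))
    counts = np.zeros(T)
    for t in range(T):
        frames_t = frame_stacks[t].astype(float)
        if window == "auto":
            w = 1
            while w < F:
                score = _mean_raw_score(model, frames_t, particles, t, w, ph, img_c, h)
                if score >= score_floor:
                    break
                w *= 2
            w = min(w, F)
        else:
            w = int(window)
        avg = running_averages(frames_t, w)

        members = [p for p in range(stack.n_particles) if stack.valid[p, t]]
        raw = np.zeros((len(members), F, 2))
        scr = np.zeros((len(members), F))
        pos2d = np.zeros((len(members), 2))
        for j, p in enumerate(members):
            part = particles[p]
            base_model, crops_xy = _reference_coeffs(model, p, t, part)
            pos2d[j] = crops_xy
            x0, y0 = (img_c + stack.offsets[p, t] - h).astype(int)
            sub = avg[:, y0 : y0 + nb, x0 : x0 + nb]
            fc = centered_fft2(sub)[:, model.mask]  # (F, m)
            norm_f = np.linalg.norm(fc, axis=1)
            mdl = base_model[None, :] * ph  # (S, m)
            norm_m = np.linalg.norm(mdl, axis=1)
            num = np.real(np.einsum("fm,sm->fs", np.conj(fc), mdl))
            d = num / np.maximum(norm_f[:, None] * norm_m[None, :], 1e-300)
            for f in range(F):
                raw[j, f], scr[j, f] = _quadratic_peak(d[f].reshape(side, side), dgrid, max_shift)
        sums[t] += scr.mean(axis=0) if members else 0.0
        counts[t] = 1 if members else 0

        smooth = _regularize(raw, pos2d, lambda_t, lambda_s, neighbor_radius)
        smooth = smooth - smooth[:, :1, :]
        for j, p in enumerate(members):
            trajectories.append(FrameTrajectory(int(p), int(t), smooth[j], scr[j]))
    frame_scores = sums  # (T, F) mean raw score per frame
    return trajectories, frame_scores


def _reference_coeffs(model: ScoreModel, p: int, t: int, part):
    """Masked model coefficients (slice * CTF * pose phase) for one projection."""
    stack = model.stack
    mat = model._tilt_mats[t]
    Q = mat @ part.matrix()
    u = (mat @ (part.pos - stack.center))[:2]
    u = u + np.array([stack.tilts[t].shift_x, stack.tilts[t].shift_y])
    in_crop = (u - stack.offsets[p, t]) / stack.binning
    sl = model.projector.slice_points(Q, model.kx, model.ky)
    ctf = model.ctf_coeffs(p, part.pos)[t]
    phase = np.exp(-2j * np.pi * (model.kx * in_crop[0] + model.ky * in_crop[1]) / stack.box)
    return sl * ctf * phase, u


def _mean_raw_score(model, frames_t, particles, t, w, ph, img_c, h):
    stack = model.stack
    nb = stack.box
    avg = running_averages(frames_t, w)
    vals = []
    for p in range(stack.n_particles):
        if not stack.valid[p, t]:
            continue
        part = particles[p]
        base_model, _ = _reference_coeffs(model, p, t, part)
        x0, y0 = (img_c + stack.offsets[p, t] - h).astype(int)
        sub = avg[:, y0 : y0 + nb, x0 : x0 + nb]
        fc = centered_fft2(sub)[:, model.mask]
        num = np.real(fc @ np.conj(base_model))
        den = np.linalg.norm(fc, axis=1) * np.linalg.norm(base_model)
        vals.append(float(np.mean(num / np.maximum(den, 1e-300))))
    return float(np.mean(vals)) if vals else 0.0


def _quadratic_peak(grid: np.ndarray, dgrid: np.ndarray, max_shift: int):
    """Sub-pixel peak of a correlation grid by 1D quadratic interpolation."""
    side = grid.shape[0]
    flat = int(np.argmax(grid))
    iy, ix = divmod(flat, side)
    peak = grid[iy, ix]
    dx = dy = 0.0
    if 0 < ix < side - 1:
        a, b, c = grid[iy, ix - 1], peak, grid[iy, ix + 1]
        denom = a - 2 * b + c
        if denom < 0:
            dx = 0.5 * (a - c) / denom
    if 0 < iy < side - 1:
        a, b, c = grid[iy - 1, ix], peak, grid[iy + 1, ix]
        denom = a - 2 * b + c
        if denom < 0:
            dy = 0.5 * (a - c) / denom
    shift = np.array([ix - max_shift + dx, iy - max_shift + dy])
    return shift, float(peak)


def _regularize(raw, pos2d, lambda_t, lambda_s, radius):
    """Closed-form quadratic smoothing of the raw trajectories of one tilt."""
    P, F, _ = raw.shape
    if P == 0:
        return raw
    Kt = _second_difference_penalty(F)
    A = sparse.identity(P * F, format="lil")
    for j in range(P):
        sl = slice(j * F, (j + 1) * F)
        A[sl, sl] = sparse.identity(F) + lambda_t * Kt
    A = A.tocsr()
    if lambda_s > 0 and P > 1:
        rows, cols, vals = [], [], []
        for i in range(P):
            for j in range(i + 1, P):
                if np.linalg.norm(pos2d[i] - pos2d[j]) <= radius:
                    for f in range(F):
                        a, b = i * F + f, j * F + f
                        rows += [a, b, a, b]
                        cols += [a, b, b, a]
                        vals += [lambda_s, lambda_s, -lambda_s, -lambda_s]
        if rows:
            A = A + sparse.csr_matrix((vals, (rows, cols)), shape=(P * F, P * F))
    out = np.empty_like(raw)
    for c in range(2):
        rhs = raw[:, :, c].reshape(-1)
        out[:, :, c] = spsolve(A.tocsc(), rhs).reshape(P, F)
    return out


def align_and_weight_frames(
    stack,
    frame_stacks: np.ndarray,
    trajectories,
    frame_weights: np.ndarray | None = None,
):
    """Replace each tilt crop by its aligned (optionally exposure-weighted) frame sum.

    Each frame crop is translated back along its refined trajectory and the
    frames are summed; with per-frame frequency weights (T, F, nb, nb),
    normalized over frames at every frequency, the sum becomes the
    exposure-weighted average (times F, preserving the tilt-image scale).
    Returns a new :class:`~spcet.stack.ProjectionStack` whose crops can be
    fed straight into reconstruction.
    """
    from .projector import centered_ifft2, shift_phase
    from .stack import ProjectionStack

    T, F, ny, nx = frame_stacks.shape
    nb = stack.box
    h = nb // 2
    img_c = np.array([nx // 2, ny // 2])
    crops = np.array(stack.crops, copy=True)
    traj_of = {(tr.particle_id, tr.tilt_index): tr for tr in trajectories}
    for (p, t), tr in traj_of.items():
        x0, y0 = (img_c + stack.offsets[p, t] - h).astype(int)
        sub = frame_stacks[t, :, y0 : y0 + nb, x0 : x0 + nb].astype(float)
        spec = centered_fft2(sub)
        for f in range(F):
            # undo the estimated drift (content moved by +shift, translate back)
            spec[f] = spec[f] * shift_phase(nb, -tr.shifts[f, 0], -tr.shifts[f, 1])
        if frame_weights is not None:
            w = frame_weights[t]  # (F, nb, nb), sums to 1 over frames
            out = (spec * w).sum(axis=0) * F
        else:
            out = spec.sum(axis=0)
        crops[p, t] = centered_ifft2(out).real.astype(np.float32)
    return ProjectionStack(
        crops=crops,
        offsets=stack.offsets,
        valid=stack.valid,
        tilts=stack.tilts,
        pixel_size=stack.pixel_size,
        tomogram_dims=stack.tomogram_dims,
        binning=stack.binning,
    )
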