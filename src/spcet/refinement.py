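"""Projection-matching score and constrained refinement.

The score ``d`` between a particle projection and a reprojection of the
reference is a normalized cross-correlation computed over a resolution band
in Fourier space; the refinement objective ``D`` is the sum of ``d`` over the
projections being refined.  Three refiners share it:

* :func:`global_search` — exhaustive orientation/position search on a coarse
  grid, with all of a particle's tilted projections scored jointly (the sum
  of per-tilt scores is maximized); an optional surface-normal prior
  restricts the search to a single in-plane angle.
* :func:`refine_fully_constrained` — per-particle local maximization over the
  six rigid parameters (three Euler angles, three translations); every
  projection pose is regenerated through the pose-composition mapping at
  every step, so no per-projection parameters are ever free.
* :func:`refine_region_geometry` — relaxes the shared tilt geometry into
  per-region corrections (tilt-axis angle, tilt angle, image shifts) to model
  beam-induced deformation, keeping the particles' 3D poses fixed.

All refiners are monotone: they never return parameters scoring below their
input (up to optimizer tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .ctf import CTFParams, ctf_eval, particle_defocus
from .geometry import (
    ParticlePose,
    RegionGrid,
    canonicalize_euler,
    euler_to_matrix,
    matrix_to_euler,
    tilt_matrix,
)
from .projector import (
    FourierProjector,
    band_mask,
    centered_fft2,
    fourier_crop_volume,
)
from .stack import ProjectionStack

__all__ = [
    "ScoreModel",
    "SearchLimits",
    "score_projection",
    "score_stack_subset",
    "global_search",
    "refine_fully_constrained",
    "refine_region_geometry",
    "refine_tilt_geometry",
]


@dataclass
class SearchLimits:
    """Half-ranges of the local searches: degrees for angles, unbinned pixels
    for in-plane shifts; ``z`` defaults to the shift range."""

    angle: float = 5.0
    shift: float = 3.0
    z: float | None = None

    @property
    def z_range(self) -> float:
        return self.shift if self.z is None else self.z


class ScoreModel:
    """Scoring context: reference projector + crops + resolution band + CTFs.

    Parameters
    ----------
    reference:
        Cubic reference volume at the stack's unbinned box size.
    stack:
        :class:`~spcet.stack.ProjectionStack` of particle crops.
    band:
        ``(low_res, high_res)`` in Angstrom; correlations use only this
        annulus, excluding the DC term, so the score is invariant to image
        scaling and offset.
    tilt_ctfs:
        Per-tilt CTF parameters; per-projection CTFs are derived by the depth
        offset at each particle's current position.
    binning:
        Fourier-crop factor applied to both reference and crops.
    """

    def __init__(
        self,
        reference: np.ndarray,
        stack: ProjectionStack,
        band: tuple[float, float] = (40.0, 8.0),
        tilt_ctfs: list[CTFParams] | None = None,
        binning: int = 1,
    ):
        if binning > 1:
            reference = fourier_crop_volume(reference, binning)
            stack = stack.binned(binning)
        self.stack = stack
        self.projector = FourierProjector(reference)
        self.binning = stack.binning
        self.pixel_size = stack.pixel_size * stack.binning
        self.band = band
        self.tilt_ctfs = tilt_ctfs
        n = stack.box
        self.mask = band_mask(n, self.pixel_size, band)
        my, mx = np.nonzero(self.mask)
        c = n // 2
        self.kx = (mx - c).astype(float)  # centered integer frequencies
        self.ky = (my - c).astype(float)
        self.k_abs = np.hypot(self.kx, self.ky) / (n * self.pixel_size)  # 1/A
        self.az = np.arctan2(self.ky, self.kx)
        self._tilt_mats = np.stack([t.matrix() for t in stack.tilts])
        self._img_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._ctf_cache: dict[int, np.ndarray] = {}

    # -- cached per-particle quantities -------------------------------------

    def image_coeffs(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        """Masked Fourier coefficients of particle ``p``'s crops and their norms."""
        if p not in self._img_cache:
            ffts = self.stack.crop_ffts(p)
            im = ffts[:, self.mask]
            self._img_cache[p] = (im, np.linalg.norm(im, axis=1))
        return self._img_cache[p]

    def ctf_coeffs(self, p: int, pos=None, ctf_offset=None) -> np.ndarray:
        """Masked per-tilt CTF values for particle ``p`` at 3D position ``pos``.

        Cached at the particle's position when no offset is supplied; the
        depth-defocus gradient across a local search range is negligible at
        these box sizes, so pose refiners reuse the cached filter.
        """
        if self.tilt_ctfs is None:
            return np.ones((self.stack.n_tilts, self.kx.size))
        if ctf_offset is None and p in self._ctf_cache:
            return self._ctf_cache[p]
        if pos is None:
            raise ValueError("position required to compute CTF coefficients")
        rows = []
        for it, tilt in enumerate(self.stack.tilts):
            base = self.tilt_ctfs[it]
            if ctf_offset is not None:
                d1, d2, dang = ctf_offset
                base = CTFParams(
                    base.df1 + d1,
                    base.df2 + d2,
                    base.astig_angle + dang,
                    base.voltage,
                    base.cs,
                    base.amplitude_contrast,
                    base.phase_shift,
                )
            cp = particle_defocus(base, tilt, pos, self.stack.pixel_size, self.stack.center)
            rows.append(ctf_eval(cp, self.k_abs, self.az))
        out = np.stack(rows)
        if ctf_offset is None:
            self._ctf_cache[p] = out
        return out

    def invalidate_caches(self) -> None:
        self._ctf_cache.clear()

    def _phase(self, shifts: np.ndarray) -> np.ndarray:
        """Masked-point phase ramps for in-crop shifts (binned px), (T, m)."""
        n = self.stack.box
        sx = np.atleast_2d(shifts)[:, 0, None]
        sy = np.atleast_2d(shifts)[:, 1, None]
        return np.exp(-2j * np.pi * (self.kx[None] * sx + self.ky[None] * sy) / n)

    # -- core score ---------------------------------------------------------

    def particle_scores(
        self,
        p: int,
        angles,
        pos,
        tilt_sel: np.ndarray | None = None,
        deltas: np.ndarray | None = None,
        ctf_offset=None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scores ``d`` of particle ``p`` at a candidate pose, per selected tilt.

        ``deltas`` is an optional (T, 4) array of per-tilt geometry
        corrections (d_alpha, d_beta, d_shift_x, d_shift_y).  Returns
        ``(d, tilt_indices)`` over the valid selected tilts.
        """
        stack = self.stack
        sel = np.arange(stack.n_tilts) if tilt_sel is None else np.asarray(tilt_sel)
        sel = sel[stack.valid[p, sel]]
        if sel.size == 0:
            return np.zeros(0), sel
        R = euler_to_matrix(angles)
        rel = np.asarray(pos, dtype=float) - stack.center
        if deltas is not None and np.any(deltas[sel, :2]):
            mats = np.stack(
                [
                    tilt_matrix(
                        stack.tilts[t].alpha + deltas[t, 0],
                        stack.tilts[t].beta + deltas[t, 1],
                    )
                    for t in sel
                ]
            )
        else:
            mats = self._tilt_mats[sel]
        Q = mats @ R
        u = mats @ rel  # (T, 3)
        shifts = u[:, :2].copy()
        for j, t in enumerate(sel):
            shifts[j, 0] += stack.tilts[t].shift_x
            shifts[j, 1] += stack.tilts[t].shift_y
            if deltas is not None:
                shifts[j] += deltas[t, 2:4]
        in_crop = (shifts - stack.offsets[p, sel]) / stack.binning

        slices = self.projector.slice_points(Q, self.kx, self.ky)
        ctf = self.ctf_coeffs(p, pos, ctf_offset)[sel]
        model = slices * ctf * self._phase(in_crop)
        im, norm_i = self.image_coeffs(p)
        im = im[sel]
        norm_i = norm_i[sel]
        norm_m = np.linalg.norm(model, axis=1)
        num = np.real(np.einsum("tm,tm->t", np.conj(im), model))
        denom = norm_i * norm_m
        d = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        return d, sel

    def particle_score_sum(self, p, angles, pos, **kw) -> float:
        d, _ = self.particle_scores(p, angles, pos, **kw)
        return float(d.sum())

    def score_table(self, particles, tilt_sel=None, deltas_for=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-(particle, tilt) score matrix and per-particle mean scores.

        ``deltas_for`` optionally maps particle index -> (T, 4) geometry
        deltas (e.g. from region refinement).
        """
        P, T = self.stack.n_particles, self.stack.n_tilts
        table = np.full((P, T), np.nan)
        agg = np.zeros(P)
        for p, part in enumerate(particles):
            deltas = deltas_for(p) if deltas_for is not None else None
            d, sel = self.particle_scores(p, part.angles, part.pos, tilt_sel, deltas)
            table[p, sel] = d
            agg[p] = d.mean() if d.size else np.nan
        return table, agg

    def tilt_selection(self, beta_window: float | None) -> np.ndarray:
        """Indices of tilts with |beta| within the window (None = all tilts)."""
        if beta_window is None:
            return np.arange(self.stack.n_tilts)
        betas = np.array([t.beta for t in self.stack.tilts])
        return np.where(np.abs(betas) <= beta_window)[0]


def score_projection(
    image: np.ndarray,
    reference,
    proj_pose,
    ctf: CTFParams | None,
    band: tuple[float, float],
    pixel_size: float,
    shift_override=None,
) -> float:
    """Normalized band-limited cross-correlation between an image and a
    reprojection of the reference at a projection pose.

    ``reference`` may be a volume or a prebuilt
    :class:`~spcet.projector.FourierProjector`.  The pose shift is interpreted
    relative to the image center, in pixels.
    """
    proj = reference if isinstance(reference, FourierProjector) else FourierProjector(reference)
    n = image.shape[-1]
    mask = band_mask(n, pixel_size, band)
    my, mx = np.nonzero(mask)
    c = n // 2
    kx, ky = (mx - c).astype(float), (my - c).astype(float)
    Q = proj_pose.matrix() if hasattr(proj_pose, "matrix") else euler_to_matrix(proj_pose)
    sl = proj.slice_points(Q, kx, ky)
    shift = shift_override if shift_override is not None else getattr(proj_pose, "shift", (0.0, 0.0))
    ph = np.exp(-2j * np.pi * (kx * shift[0] + ky * shift[1]) / n)
    model = sl * ph
    if ctf is not None:
        k_abs = np.hypot(kx, ky) / (n * pixel_size)
        model = model * ctf_eval(ctf, k_abs, np.arctan2(ky, kx))
    im = centered_fft2(np.asarray(image, dtype=float))[mask]
    denom = np.linalg.norm(im) * np.linalg.norm(model)
    if denom == 0:
        return 0.0
    return float(np.real(np.vdot(im, model)) / denom)


def score_stack_subset(
    model: ScoreModel,
    particles,
    members,
    tilt_ctfs,
    ctf_offset=None,
    deltas=None,
    tilt_sel=None,
) -> float:
    """Summed objective D over a subset of particles (used by CTF refinement).

    ``ctf_offset = (d_df1, d_df2, d_astig_angle)`` is applied to the per-tilt
    CTFs before the per-particle depth offset.
    """
    total = 0.0
    for p in members:
        part = particles[p]
        total += model.particle_score_sum(
            int(p), part.angles, part.pos, tilt_sel=tilt_sel, deltas=deltas, ctf_offset=ctf_offset
        )
    return total


# ---------------------------------------------------------------------------
# Global (exhaustive) constrained search
# ---------------------------------------------------------------------------


def _orientation_grid(angular_step: float) -> list[tuple[float, float, float]]:
    thetas = np.arange(-180.0, 180.0, angular_step)
    phis = np.arange(0.0, 180.0 + 1e-9, angular_step)
    psis = np.arange(-180.0, 180.0, angular_step)
    grid = []
    for phi in phis:
        if phi < 1e-9 or phi > 180.0 - 1e-9:
            for theta in thetas:
                grid.append((theta, phi, 0.0))
        else:
            for theta in thetas:
                for psi in psis:
                    grid.append((theta, phi, psi))
    return grid


def _prior_orientations(normal, angular_step: float) -> list[tuple[float, float, float]]:
    nx, ny, nz = np.asarray(normal, dtype=float) / np.linalg.norm(normal)
    phi = float(np.degrees(np.arccos(np.clip(nz, -1, 1))))
    theta = float(np.degrees(np.arctan2(ny, nx)))
    return [(theta, phi, float(psi)) for psi in np.arange(-180.0, 180.0, angular_step)]


def global_search(
    model: ScoreModel,
    init_positions,
    angular_step: float = 15.0,
    shift_range: float = 2.0,
    normal_priors=None,
    tilt_sel: np.ndarray | None = None,
):
    """Exhaustive constrained orientation/position search.

    For every candidate orientation the per-tilt reprojections follow from the
    pose-composition mapping; the sum of per-tilt band-limited correlations is
    evaluated on an integer 3D displacement grid of half-range ``shift_range``
    voxels around each particle's initial position.  With a surface-normal
    prior only the in-plane angle is scanned.  Ties break in favor of the
    first grid point.

    Returns ``(poses, n_evaluations)`` where ``n_evaluations`` counts
    orientation x tilt reprojection evaluations.
    """
    if angular_step < 1.0:
        raise ValueError("angular_step must be >= 1 degree")
    stack = model.stack
    sel_all = np.arange(stack.n_tilts) if tilt_sel is None else np.asarray(tilt_sel)
    init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
    P = init_positions.shape[0]
    mats = model._tilt_mats

    # integer displacement grid
    r = int(round(shift_range))
    ax = np.arange(-r, r + 1, dtype=float)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    disp = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])  # (S, 3)

    n_eval = 0
    results = []
    for p in range(P):
        sel = sel_all[stack.valid[p, sel_all]]
        if normal_priors is not None:
            grid = _prior_orientations(normal_priors[p], angular_step)
        else:
            grid = _orientation_grid(angular_step)
        rel = init_positions[p] - stack.center
        base_u = mats[sel] @ rel  # (T, 3)
        tilt_shifts = np.array(
            [(stack.tilts[t].shift_x, stack.tilts[t].shift_y) for t in sel]
        )
        base_in_crop = (base_u[:, :2] + tilt_shifts - stack.offsets[p, sel]) / stack.binning
        ddisp = np.einsum("tij,sj->tsi", mats[sel], disp)[..., :2] / stack.binning  # (T, S, 2)
        im, norm_i = model.image_coeffs(p)
        im, norm_i = im[sel], norm_i[sel]
        ctf = model.ctf_coeffs(p, init_positions[p])[sel]

        best = (-np.inf, 0, 0)  # (score, orient idx, disp idx)
        for io, ang in enumerate(grid):
            R = euler_to_matrix(ang)
            Q = mats[sel] @ R
            slices = model.projector.slice_points(Q, model.kx, model.ky)
            n_eval += len(sel)
            model_c = slices * ctf
            norm_m = np.linalg.norm(model_c, axis=1)
            # correlate against all displacements via phase ramps
            shifts = base_in_crop[:, None, :] + ddisp  # (T, S, 2)
            n = stack.box
            ph = np.exp(
                -2j
                * np.pi
                * (
                    model.kx[None, None, :] * shifts[..., 0, None]
                    + model.ky[None, None, :] * shifts[..., 1, None]
                )
                / n
            )
            num = np.real(np.einsum("tm,tsm->ts", np.conj(im) * 1.0, model_c[:, None, :] * ph))
            denom = (norm_i * norm_m)[:, None]
            d = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
            total = d.sum(axis=0)  # (S,)
            s_best = int(np.argmax(total))
            if total[s_best] > best[0]:
                best = (float(total[s_best]), io, s_best)
        ang = grid[best[1]]
        pos = init_positions[p] + disp[best[2]]
        d_final, _ = model.particle_scores(p, ang, pos, tilt_sel=sel)
        results.append(
            ParticlePose(p, pos, canonicalize_euler(ang), float(d_final.mean()))
        )
    return results, n_eval


# ---------------------------------------------------------------------------
# Local constrained refiners
# ---------------------------------------------------------------------------

_COORD_TOL_ANGLE = 0.01  # degrees
_COORD_TOL_SHIFT = 0.01  # pixels


def _coordinate_maximize(objective, x0, half_ranges, tols, n_sweeps=2):
    """Coordinate-wise bounded 1D maximization, monotone by construction.

    Each coordinate is maximized with a derivative-free bounded scalar search
    inside ``x0[i] +/- half_ranges[i]``; a proposed move is only accepted if
    it does not lower the objective.  Coordinates with zero half-range are
    skipped.  Returns ``(x_best, f_best, f_start)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    f_start = objective(x)
    f_best = f_start
    for _ in range(n_sweeps):
        for i, hr in enumerate(half_ranges):
            if hr <= 0:
                continue
            lo, hi = x0[i] - hr, x0[i] + hr

            def neg(v, i=i):
                xt = x.copy()
                xt[i] = v
                return -objective(xt)

            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": tols[i]})
            if -res.fun > f_best:
                f_best = -res.fun
                x[i] = res.x
    return x, f_best, f_start


def refine_fully_constrained(
    model: ScoreModel,
    particles,
    limits: SearchLimits = SearchLimits(),
    tilt_window: float | None = None,
    maxfev: int = 600,
):
    """Six-parameter local refinement of every particle's rigid transformation.

    All projection poses are regenerated through the pose-composition mapping
    at every objective evaluation (the translations are constrained too: the
    per-tilt shifts follow from the single 3D position).  The rotation is
    parametrized as a rotation-vector perturbation about the current
    orientation, which keeps the search well conditioned at any pose (Euler
    coordinates degenerate near phi = 0/180); the maximizer is a bounded
    derivative-free direction-set (Powell) search.  The per-particle
    aggregate score never decreases; a particle whose objective is
    non-finite is flagged (``score = nan``) and keeps its input pose.

    Returns ``(new_particles, info)`` with per-particle score gains.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    sel = model.tilt_selection(tilt_window)
    out = []
    gains = np.zeros(len(particles))
    for p, part in enumerate(particles):
        R0 = euler_to_matrix(part.angles)

        def objective(x, p=p, R0=R0, part=part):
            R = R0 @ Rotation.from_rotvec(np.deg2rad(x[:3])).as_matrix()
            return model.particle_score_sum(p, matrix_to_euler(R), part.pos + x[3:], tilt_sel=sel)

        f0 = objective(np.zeros(6))
        if not np.isfinite(f0):
            out.append(ParticlePose(part.particle_id, part.pos, part.angles, np.nan))
            continue
        if limits.angle <= 0 and limits.shift <= 0 and limits.z_range <= 0:
            out.append(ParticlePose(part.particle_id, part.pos, part.angles, part.score))
            continue
        bounds = [(-limits.angle, limits.angle)] * 3 + [
            (-limits.shift, limits.shift),
            (-limits.shift, limits.shift),
            (-limits.z_range, limits.z_range),
        ]
        res = minimize(
            lambda x: -objective(x),
            np.zeros(6),
            method="Powell",
            bounds=bounds,
            options={"xtol": _COORD_TOL_ANGLE, "ftol": 1e-9, "maxfev": maxfev},
        )
        n_valid = int(model.stack.valid[p, sel].sum())
        if -res.fun > f0:  # monotone guard
            R = R0 @ Rotation.from_rotvec(np.deg2rad(res.x[:3])).as_matrix()
            out.append(
                ParticlePose(
                    part.particle_id,
                    part.pos + res.x[3:],
                    matrix_to_euler(R),
                    float(-res.fun) / max(n_valid, 1),
                )
            )
            gains[p] = float(-res.fun) - f0
        else:
            out.append(ParticlePose(part.particle_id, part.pos, part.angles, f0 / max(n_valid, 1)))
    return out, {"score_gain": gains, "tilt_selection": sel}


def refine_region_geometry(
    model: ScoreModel,
    particles,
    grid: RegionGrid,
    limits: SearchLimits = SearchLimits(angle=0.5, shift=6.0),
    min_particles: int = 5,
    tilt_window: float | None = None,
    n_sweeps: int = 2,
):
    """Refine per-region, per-tilt geometry corrections (deformation model).

    For each region and tilt, the summed score of the region's particles at
    that tilt is maximized over ``(d_alpha, d_beta, d_shift_x, d_shift_y)``
    within the search limits, holding all particle poses fixed.  Regions with
    fewer than ``min_particles`` members keep zero corrections and are
    reported with a warning.

    Returns ``(deltas, info)``; ``deltas`` has shape (G, T, 4).
    """
    stack = model.stack
    sel = model.tilt_selection(tilt_window)
    region_ids = grid.assign([p.pos for p in particles])
    G, T = grid.n_regions, stack.n_tilts
    deltas = np.zeros((G, T, 4))
    gains = np.zeros((G, T))
    skipped = []
    for g in range(G):
        members = np.where(region_ids == g)[0]
        if members.size == 0:
            continue
        if members.size < min_particles:
            skipped.append(g)
            warnings.warn(
                f"region {g}: {members.size} particles < minimum {min_particles}; "
                "geometry correction kept at zero"
            )
            continue
        mem_parts = [(int(p), particles[p]) for p in members]
        for t in sel:
            active = [(p, part) for p, part in mem_parts if stack.valid[p, t]]
            if not active:
                continue

            def objective(x, t=t, active=active):
                dl = np.zeros((T, 4))
                dl[t] = x
                total = 0.0
                for p, part in active:
                    d, _ = model.particle_scores(
                        p, part.angles, part.pos, tilt_sel=np.array([t]), deltas=dl
                    )
                    total += float(d.sum())
                return total

            x0 = np.zeros(4)
            half = [limits.angle, limits.angle, limits.shift, limits.shift]
            tols = [_COORD_TOL_ANGLE] * 2 + [_COORD_TOL_SHIFT] * 2
            x, f_best, f_start = _coordinate_maximize(objective, x0, half, tols, n_sweeps)
            deltas[g, t] = x
            gains[g, t] = f_best - f_start
    if grid.geom_deltas is None:
        grid.init_deltas(T)
    grid.geom_deltas[:] = deltas
    return deltas, {"score_gain": gains, "skipped_regions": skipped, "region_ids": region_ids}


def refine_tilt_geometry(
    model: ScoreModel,
    particles,
    limits: SearchLimits = SearchLimits(angle=0.5, shift=6.0),
    tilt_window: float | None = None,
):
    """Global per-tilt geometry refinement == region refinement on a 1x1x1 grid."""
    grid = RegionGrid(1, 1, 1, model.stack.tomogram_dims)
    deltas, info = refine_region_geometry(
        model, particles, grid, limits, min_particles=1, tilt_window=tilt_window
    )
    return deltas[0], info
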