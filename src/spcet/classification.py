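"""Constrained 3D classification from 2D tilted projections.

Heterogeneity is resolved by expectation-maximization over K reference
volumes.  The tilt-geometry constraint is imposed at two points: class
membership is randomized over whole particles (never individual
projections), and per-particle occupancies are obtained by averaging the
per-projection occupancies of each particle with Gaussian weights centered
on the zero-tilt image (s.d. 6 degrees), so all projections of a particle
share one class distribution.  Occupancy softmaxes always use the *global*
score statistics (mean and s.d. over every projection in the dataset), never
per-bundle statistics.  Score-based weights are deliberately not used in the
occupancy averaging (at tomographic SNR they overfit); the full tilt range
participates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import FourierProjector
from .reconstruction import reconstruct
from .refinement import ScoreModel

__all__ = [
    "ClassModel",
    "projection_occupancies",
    "particle_occupancies",
    "classify_constrained",
    "classify_unconstrained",
    "match_class_labels",
]


@dataclass
class ClassModel:
    """State of a K-class decomposition."""

    n_classes: int
    occupancies: np.ndarray  # (P, K), rows sum to 1
    class_maps: list[np.ndarray]
    score_mean: float
    score_std: float
    iteration: int
    rng_seed: int
    history: list[dict] = field(default_factory=list)

    @property
    def populations(self) -> np.ndarray:
        return self.occupancies.sum(axis=0)

    @property
    def assignments(self) -> np.ndarray:
        return np.argmax(self.occupancies, axis=1)


def projection_occupancies(
    scores: np.ndarray,
    global_mean: float,
    global_std: float,
    sigma_floor: float = 1e-6,
) -> np.ndarray:
    """Softmax occupancies of standardized per-class scores.

    ``scores`` has shape (..., K); the occupancy of class k is proportional
    to ``exp((s_k - mean) / max(std, floor))`` with the *global* statistics,
    which makes the result invariant to a joint affine rescaling of all
    scores.
    """
    s = np.asarray(scores, dtype=float)
    if s.shape[-1] < 1:
        raise ValueError("at least one class required")
    z = (s - global_mean) / max(global_std, sigma_floor)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def particle_occupancies(
    proj_occ: np.ndarray,
    betas: np.ndarray,
    sigma_tilt: float = 6.0,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Tilt-weighted average of per-projection occupancies, one row per particle.

    Weights are Gaussian in the tilt angle, centered at 0 degrees with s.d.
    ``sigma_tilt`` (degrees), renormalized over each particle's available
    tilts; ``sigma_tilt = inf`` gives the plain mean.  The result rows sum
    to 1, and every projection of the particle inherits this shared
    distribution.
    """
    occ = np.asarray(proj_occ, dtype=float)  # (P, T, K)
    betas = np.asarray(betas, dtype=float)
    if np.isinf(sigma_tilt):
        w = np.ones_like(betas)
    else:
        w = np.exp(-(betas**2) / (2.0 * sigma_tilt**2))
    W = np.broadcast_to(w, occ.shape[:2]).astype(float).copy()
    if valid is not None:
        W = W * valid
    W = W / np.maximum(W.sum(axis=1, keepdims=True), 1e-300)
    out = np.einsum("pt,ptk->pk", W, occ)
    return out / np.maximum(out.sum(axis=1, keepdims=True), 1e-300)


def _class_contrast_std(scores: np.ndarray, finite: np.ndarray) -> float:
    """Global score scale used as the softmax temperature.

    The softmax is invariant to per-projection score offsets, so the relevant
    global statistic is the spread of the cross-class score residuals (the
    raw score spread is dominated by tilt-angle and dose effects common to
    all classes, which would wash the class contrast out).
    """
    if scores.shape[-1] < 2:
        return 1.0
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        resid = scores - np.nanmean(scores, axis=-1, keepdims=True)
        return float(np.nanstd(resid[finite]))


def _spherical_mask(box: int, center, radius: float) -> np.ndarray:
    ax = np.arange(box) - box // 2
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    cx, cy, cz = center
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    return 0.5 * (1.0 - np.tanh(r - radius))  # soft edge, ~1 voxel


def classify_constrained(
    model: ScoreModel,
    particles,
    n_classes: int,
    n_iter: int = 30,
    mode: str = "no-alignment",
    focus_center=None,
    focus_radius: float | None = None,
    tilt_ctfs=None,
    sigma_tilt: float = 6.0,
    rng_seed: int = 0,
    min_population: float = 1.0,
    conv_tol: float = 1e-4,
    align_limits=None,
):
    """K-class constrained classification of a projection stack.

    Initialization assigns whole particles (never projections) randomly to
    the K seeds; each iteration scores every projection against every class
    reconstruction, converts scores to per-projection occupancies with the
    global score statistics, averages them into per-particle occupancies with
    the 0-degree-centered Gaussian tilt weights, and rebuilds each class map
    with occupancy-weighted insertion.  ``mode="with-alignment"`` re-refines
    each particle against its best class every iteration;
    ``mode="no-alignment"`` keeps poses fixed.  With a focus mask, scoring
    uses class maps whose differences from the consensus are confined to the
    spherical mask region.

    An emptied class (population below ``min_population``) is reseeded from a
    random half of the largest class, which is logged in the history.
    Deterministic for a fixed ``rng_seed``.

    Returns a :class:`ClassModel` (its ``class_maps`` are the final
    occupancy-weighted reconstructions).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if mode not in ("no-alignment", "with-alignment"):
        raise ValueError(f"unknown mode {mode!r}")
    stack = model.stack
    P = stack.n_particles
    K = n_classes
    tilt_ctfs = tilt_ctfs if tilt_ctfs is not None else model.tilt_ctfs
    rng = np.random.default_rng(rng_seed)

    occ = np.zeros((P, K))
    occ[np.arange(P), rng.integers(0, K, size=P)] = 1.0
    betas = np.array([t.beta for t in stack.tilts])

    mask = None
    if focus_center is not None and focus_radius is not None:
        mask = _spherical_mask(stack.box, np.asarray(focus_center, dtype=float), focus_radius)

    cur_particles = list(particles)
    history: list[dict] = []
    class_maps: list[np.ndarray] = []
    gmean, gstd = 0.0, 1.0

    for it in range(n_iter):
        class_maps = []
        for k in range(K):
            m, _, _, _ = reconstruct(
                stack, cur_particles, tilt_ctfs, particle_weights=occ[:, k]
            )
            class_maps.append(m)
        if mask is not None:
            consensus = sum(
                occ[:, k].sum() / P * class_maps[k] for k in range(K)
            )
            score_maps = [consensus + mask * (m - consensus) for m in class_maps]
        else:
            score_maps = class_maps

        if mode == "with-alignment":
            from .refinement import SearchLimits, refine_fully_constrained

            best_k = np.argmax(occ, axis=1)
            limits = align_limits or SearchLimits(angle=2.0, shift=1.0)
            new_parts = list(cur_particles)
            for k in range(K):
                sub = np.where(best_k == k)[0]
                if sub.size == 0:
                    continue
                saved = model.projector
                model.projector = FourierProjector(score_maps[k])
                refined, _ = refine_fully_constrained(
                    model, [cur_particles[p] for p in sub], limits
                )
                model.projector = saved
                for j, p in enumerate(sub):
                    new_parts[p] = refined[j]
            cur_particles = new_parts

        # score every projection against every class
        T = stack.n_tilts
        scores = np.full((P, T, K), np.nan)
        saved = model.projector
        for k in range(K):
            model.projector = FourierProjector(score_maps[k])
            for p in range(P):
                part = cur_particles[p]
                d, sel = model.particle_scores(p, part.angles, part.pos)
                scores[p, sel, k] = d
        model.projector = saved

        finite = np.isfinite(scores)
        gmean = float(scores[finite].mean())
        gstd = _class_contrast_std(scores, finite)
        proj_occ = projection_occupancies(np.nan_to_num(scores, nan=gmean), gmean, gstd)
        new_occ = particle_occupancies(proj_occ, betas, sigma_tilt, valid=stack.valid)

        change = float(np.abs(new_occ - occ).mean())
        occ = new_occ

        # reseed empty classes from the largest one
        pops = occ.sum(axis=0)
        reseeded = []
        for k in range(K):
            if pops[k] < min_population:
                big = int(np.argmax(pops))
                members = np.where(np.argmax(occ, axis=1) == big)[0]
                take = rng.choice(members, size=max(1, members.size // 2), replace=False)
                occ[take] = 0.0
                occ[take, k] = 1.0
                pops = occ.sum(axis=0)
                reseeded.append(k)
        history.append(
            {
                "iteration": it,
                "populations": pops.copy(),
                "mean_occ_change": change,
                "reseeded": reseeded,
                "score_mean": gmean,
                "score_std": gstd,
            }
        )
        if change < conv_tol and not reseeded and it > 0:
            break

    return ClassModel(
        n_classes=K,
        occupancies=occ,
        class_maps=class_maps,
        score_mean=gmean,
        score_std=gstd,
        iteration=len(history),
        rng_seed=rng_seed,
        history=history,
    )


def classify_unconstrained(
    model: ScoreModel,
    particles,
    n_classes: int,
    n_iter: int = 30,
    tilt_ctfs=None,
    rng_seed: int = 0,
    conv_tol: float = 1e-4,
):
    """Per-projection classification with the tilt constraints disabled.

    Every projection is soft-assigned independently (random initial
    per-projection memberships, no particle-level averaging), and class maps
    are rebuilt with per-projection occupancy weights.  This is the
    uncontrolled baseline the constrained mode is compared against at
    tomographic SNR.

    Returns ``(proj_occ (P, T, K), class_maps, history)``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    stack = model.stack
    P, T, K = stack.n_particles, stack.n_tilts, n_classes
    tilt_ctfs = tilt_ctfs if tilt_ctfs is not None else model.tilt_ctfs
    rng = np.random.default_rng(rng_seed)
    occ = np.zeros((P, T, K))
    occ[np.arange(P)[:, None], np.arange(T)[None, :], rng.integers(0, K, size=(P, T))] = 1.0
    history = []
    class_maps: list[np.ndarray] = []
    for it in range(n_iter):
        class_maps = []
        for k in range(K):
            m, _, _, _ = reconstruct(
                stack, particles, tilt_ctfs, particle_weights=occ[:, :, k]
            )
            class_maps.append(m)
        scores = np.full((P, T, K), np.nan)
        saved = model.projector
        for k in range(K):
            model.projector = FourierProjector(class_maps[k])
            for p in range(P):
                part = particles[p]
                d, sel = model.particle_scores(p, part.angles, part.pos)
                scores[p, sel, k] = d
        model.projector = saved
        finite = np.isfinite(scores)
        gmean = float(scores[finite].mean())
        gstd = _class_contrast_std(scores, finite)
        new_occ = projection_occupancies(np.nan_to_num(scores, nan=gmean), gmean, gstd)
        change = float(np.abs(new_occ - occ).mean())
        occ = new_occ
        history.append({"iteration": it, "mean_occ_change": change})
        if change < conv_tol and it > 0:
            break
    return occ, class_maps, history


def match_class_labels(assignments: np.ndarray, truth: np.ndarray, n_classes: int):
    """Best-permutation accuracy of class assignments against ground truth."""
    from itertools import permutations

    best_acc, best_perm = 0.0, None
    for perm in permutations(range(n_classes)):
        mapped = np.array([perm[a] for a in assignments])
        acc = float((mapped == truth).mean())
        if acc > best_acc:
            best_acc, best_perm = acc, perm
    return best_acc, best_perm
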