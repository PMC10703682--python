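"""Direct Fourier-inversion 3D reconstruction, bundle merging, FSC and
score-driven exposure weighting.

Each particle projection's CTF-multiplied transform is inserted as a central
slice into a complex numerator volume (trilinear gridding); the squared CTF
(times any weights) accumulates into a denominator volume.  The map is the
Wiener-normalized ratio.  Partial reconstructions are plain sums, so merging
is commutative and associative — the property the bundle-parallel
architecture relies on: any grouping of the projections into bundles yields
the same map.

Half-maps are built by splitting particles by id parity; resolution is read
from the Fourier shell correlation at the 0.143 crossing (linear
interpolation between shells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctf import particle_defocus, ctf_eval
from .geometry import GeometryDelta, compose_projection_pose
from .projector import centered_fft2, freq_grid_2d
from .stack import ProjectionStack

__all__ = [
    "PartialReconstruction",
    "insert_projections",
    "normalize_map",
    "merge_bundles",
    "reconstruct",
    "fsc",
    "fsc_resolution",
    "exposure_weights",
]


@dataclass
class PartialReconstruction:
    """Unnormalized Fourier accumulation from a subset of projections."""

    num: np.ndarray  # (n, n, n) complex
    den: np.ndarray  # (n, n, n) float, >= 0
    n_particles: int = 0
    half_set: int = -1  # 0/1, or -1 for combined

    @classmethod
    def empty(cls, box: int, half_set: int = -1) -> "PartialReconstruction":
        return cls(
            np.zeros((box, box, box), dtype=complex),
            np.zeros((box, box, box)),
            0,
            half_set,
        )

    def __iadd__(self, other: "PartialReconstruction") -> "PartialReconstruction":
        if self.num.shape != other.num.shape:
            raise ValueError(
                f"cannot merge reconstructions of box {self.num.shape[0]} and {other.num.shape[0]}"
            )
        self.num += other.num
        self.den += other.den
        self.n_particles += other.n_particles
        return self


def insert_projections(
    partial: PartialReconstruction,
    images: np.ndarray,
    orientations: np.ndarray,
    shifts: np.ndarray | None = None,
    ctfs: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> None:
    """Insert projection images as central slices (trilinear gridding).

    ``images`` (B, n, n) real; ``orientations`` (B, 3, 3) map reference to lab
    frame; ``shifts`` (B, 2) are removed (the particle is re-centered) before
    insertion; ``ctfs`` (B, n, n) are centered CTF grids (num gets ``I*CTF``,
    den gets ``CTF^2``, i.e. Wiener-style phase flipping with amplitude
    weighting); ``weights`` may be scalar per projection (B,) or per-frequency
    (B, n, n).
    """
    images = np.asarray(images, dtype=float)
    B, n, _ = images.shape
    Q = np.asarray(orientations, dtype=float)
    specs = centered_fft2(images)
    c = n // 2
    k = np.arange(n, dtype=float) - c
    KX = k[None, None, :]
    KY = k[None, :, None]
    if shifts is not None:
        sh = np.asarray(shifts, dtype=float)
        ph = np.exp(
            2j * np.pi * (KX * sh[:, 0, None, None] + KY * sh[:, 1, None, None]) / n
        )
        specs = specs * ph
    if ctfs is not None:
        ctfs = np.asarray(ctfs, dtype=float)
        data = specs * ctfs
        wts = ctfs * ctfs
    else:
        data = specs
        wts = np.ones_like(images)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.ndim == 1:
            w = w[:, None, None]
        data = data * w
        wts = wts * w

    # sample points Q^T (kx, ky, 0) for every pixel of every slice
    r0 = Q[:, 0, :][:, None, None, :]
    r1 = Q[:, 1, :][:, None, None, :]
    pts = KX[..., None] * r0 + KY[..., None] * r1  # (B, n, n, 3) -> (qx, qy, qz)
    coords = pts[..., ::-1] + c  # (z, y, x) array indices
    base = np.floor(coords).astype(np.int64)
    frac = coords - base

    num, den = partial.num, partial.den
    flat_num = num.reshape(-1)
    flat_den = den.reshape(-1)
    dvals = data.reshape(-1)
    wvals = wts.reshape(-1)
    b0 = base.reshape(-1, 3)
    f = frac.reshape(-1, 3)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = b0 + (dz, dy, dx)
                ok = np.all((idx >= 0) & (idx < n), axis=1)
                w8 = (
                    (dz * f[:, 0] + (1 - dz) * (1 - f[:, 0]))
                    * (dy * f[:, 1] + (1 - dy) * (1 - f[:, 1]))
                    * (dx * f[:, 2] + (1 - dx) * (1 - f[:, 2]))
                )
                flat = (idx[:, 0] * n + idx[:, 1]) * n + idx[:, 2]
                np.add.at(flat_num, flat[ok], dvals[ok] * w8[ok])
                np.add.at(flat_den, flat[ok], wvals[ok] * w8[ok])


def normalize_map(partial: PartialReconstruction, wiener_frac: float = 0.01) -> np.ndarray:
    """Wiener-normalized real-space map from an accumulated reconstruction.

    The Wiener constant is ``wiener_frac`` times the mean of the nonzero
    denominator (a small-denominator regularizer, not a sharpening filter).
    """
    den = partial.den
    nz = den[den > 0]
    w = wiener_frac * float(nz.mean()) if nz.size else 1.0
    ratio = partial.num / (den + w)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ratio))).real
    return vol


def merge_bundles(partials) -> PartialReconstruction:
    """Sum partial reconstructions; bit-identical for any input order.

    Floating-point addition is not associative, so the partials are first
    brought into a canonical order (content hash) — any permutation of the
    same bundles then produces the exact same map.
    """
    import hashlib

    partials = list(partials)
    if not partials:
        raise ValueError("nothing to merge")
    partials = sorted(
        partials, key=lambda p: hashlib.sha1(p.num.tobytes() + p.den.tobytes()).digest()
    )
    out = PartialReconstruction.empty(partials[0].num.shape[0])
    for p in partials:
        out += p
    return out


def reconstruct(
    stack: ProjectionStack,
    particles,
    tilt_ctfs=None,
    tilt_freq_weights: np.ndarray | None = None,
    particle_weights: np.ndarray | None = None,
    wiener_frac: float = 0.01,
    region_deltas=None,
    region_ids=None,
    particle_subset=None,
):
    """Reconstruct half maps and the combined map from a projection stack.

    Poses of every projection are regenerated from the tilt geometry and the
    particle poses through the pose-composition mapping (plus optional
    per-region corrections).  ``tilt_freq_weights`` (T, n, n) applies
    per-tilt frequency weights (exposure weighting); ``particle_weights``
    (P,) or (P, T) applies scalar weights (e.g. class occupancies).

    Returns ``(map, half_map_0, half_map_1, combined_partial)``.
    """
    box = stack.box
    halves = [PartialReconstruction.empty(box, h) for h in (0, 1)]
    n = box
    center = stack.center
    idxs = range(stack.n_particles) if particle_subset is None else particle_subset
    for p in idxs:
        part = particles[p]
        sel = np.where(stack.valid[p])[0]
        if sel.size == 0:
            continue
        imgs = stack.crops[p, sel].astype(float)
        Qs = np.empty((sel.size, 3, 3))
        shs = np.empty((sel.size, 2))
        ctf_grids = None if tilt_ctfs is None else np.empty((sel.size, n, n))
        kx, ky, kabs, az = freq_grid_2d(n, stack.pixel_size * stack.binning)
        for j, t in enumerate(sel):
            delta = GeometryDelta()
            if region_deltas is not None and region_ids is not None:
                da, db, dx, dy = region_deltas[region_ids[p], t]
                delta = GeometryDelta(da, db, dx, dy)
            pose = compose_projection_pose(stack.tilts[t], part, delta, center)
            Qs[j] = pose.matrix()
            shs[j] = (np.asarray(pose.shift) - stack.offsets[p, t]) / stack.binning
            if tilt_ctfs is not None:
                cp = particle_defocus(
                    tilt_ctfs[t], stack.tilts[t], part.pos, stack.pixel_size, center
                )
                ctf_grids[j] = ctf_eval(cp, kabs, az)
        w = None
        if tilt_freq_weights is not None:
            w = tilt_freq_weights[sel]
        if particle_weights is not None:
            pw = np.asarray(particle_weights)
            scal = pw[p, sel] if pw.ndim == 2 else np.full(sel.size, pw[p])
            w = scal[:, None, None] * (w if w is not None else 1.0)
            if np.ndim(w) == 1:
                w = None
        half = halves[int(part.particle_id) % 2]
        insert_projections(half, imgs, Qs, shs, ctf_grids, w)
        half.n_particles += 1
    combined = merge_bundles(halves)
    return (
        normalize_map(combined, wiener_frac),
        normalize_map(halves[0], wiener_frac),
        normalize_map(halves[1], wiener_frac),
        combined,
    )


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------


def fsc(half1: np.ndarray, half2: np.ndarray, pixel_size: float):
    """Fourier shell correlation between two maps.

    Returns ``(freqs, curve)`` with freqs in 1/Angstrom (shell centers).
    """
    if half1.shape != half2.shape:
        raise ValueError("maps must have equal dimensions")
    n = half1.shape[0]
    F1 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(half1)))
    F2 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(half2)))
    c = n // 2
    ax = np.arange(n) - c
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    shell = np.minimum(np.rint(r).astype(int), c)
    ns = c + 1
    cross = np.zeros(ns, dtype=complex)
    p1 = np.zeros(ns)
    p2 = np.zeros(ns)
    np.add.at(cross, shell.ravel(), (F1 * np.conj(F2)).ravel())
    np.add.at(p1, shell.ravel(), (np.abs(F1) ** 2).ravel())
    np.add.at(p2, shell.ravel(), (np.abs(F2) ** 2).ravel())
    denom = np.sqrt(p1 * p2)
    curve = np.where(denom > 0, np.real(cross) / np.maximum(denom, 1e-300), 0.0)
    freqs = np.arange(ns) / (n * pixel_size)
    return freqs[1:], curve[1:]


def fsc_resolution(freqs, curve, threshold: float = 0.143) -> float:
    """Resolution (Angstrom) at the first crossing of the threshold.

    Linear interpolation between shells; if the curve never drops below the
    threshold the Nyquist resolution is returned.
    """
    curve = np.asarray(curve)
    freqs = np.asarray(freqs)
    below = np.where(curve < threshold)[0]
    if below.size == 0:
        return float(1.0 / freqs[-1])
    i = below[0]
    if i == 0:
        return float(np.inf)
    f0, f1 = freqs[i - 1], freqs[i]
    c0, c1 = curve[i - 1], curve[i]
    f_cross = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return float(1.0 / f_cross)


# ---------------------------------------------------------------------------
# Score-driven exposure weights
# ---------------------------------------------------------------------------


def exposure_weights(
    mean_scores,
    freqs,
    b_ref: float = 0.03,
    sensitivity: float = 1.0,
    sigma_floor: float = 1e-6,
):
    """Per-unit frequency weights from per-unit mean scores.

    Each unit (a frame or a tilt) gets a Gaussian falloff ``w_u(k) =
    exp(-k^2 / (4 b_u))`` whose width parameter ``b_u = b_ref *
    exp(sensitivity * z_u)`` increases monotonically with the unit's
    standardized mean score ``z_u`` — higher-scoring (less damaged) units
    fall off more slowly and keep more high-frequency contribution.  Weights
    are normalized so they sum to 1 over units at every frequency;
    all-equal scores give exactly uniform weights.

    Parameters
    ----------
    mean_scores : (U,) per-unit mean particle scores.
    freqs : spatial frequencies in 1/Angstrom (any shape).
    b_ref : falloff width (1/Angstrom^2) of an average unit; the default is
        equivalent to a ~33 Angstrom^2 B-factor envelope.

    Returns
    -------
    (U, *freqs.shape) weights summing to 1 over the first axis.
    """
    s = np.asarray(mean_scores, dtype=float)
    if s.size < 1:
        raise ValueError("at least one unit required")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    k = np.asarray(freqs, dtype=float)
    sd = s.std()
    if sd < sigma_floor:
        shape = (s.size,) + k.shape
        return np.full(shape, 1.0 / s.size)
    z = (s - s.mean()) / sd
    b = b_ref * np.exp(sensitivity * z)
    w = np.exp(-k[None, ...] ** 2 / (4.0 * b.reshape((-1,) + (1,) * k.ndim)))
    return w / w.sum(axis=0, keepdims=True)


def tilt_exposure_weight_grids(mean_scores, n: int, pixel_size: float, **kw) -> np.ndarray:
    """Exposure weights evaluated on the centered 2D frequency grid of a crop."""
    _, _, kabs, _ = freq_grid_2d(n, pixel_size)
    return exposure_weights(mean_scores, kabs, **kw)
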