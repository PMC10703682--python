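"""Synthetic tilt-series generator with known ground truth.

Emulates, with controllable statistics, the features of real tomographic data
that the refinement, reconstruction, picking and classification modules rely
on: a smooth multi-sphere phantom (optionally in two structural variants for
classification benchmarks), particles at known random poses, tilted
projections with per-particle CTF, dose-dependent amplitude/B-factor decay
and ``cos(beta)`` thickness attenuation, additive white Gaussian noise at a
target SNR, per-region geometric perturbations standing in for beam-induced
deformation, per-tilt defocus offsets, and per-tilt video frames with drift.

SNR is defined as signal variance over noise variance inside the particle
boxes.  All outputs are deterministic for a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ctf import CTFParams, ctf_eval, particle_defocus
from .geometry import (
    GeometryDelta,
    ParticlePose,
    RegionGrid,
    TiltGeometry,
    compose_projection_pose,
    matrix_to_euler,
    volume_center,
)
from .projector import FourierProjector, centered_ifft2, freq_grid_2d, shift_phase

__all__ = [
    "SphereComponent",
    "DoseModel",
    "DeformationModel",
    "FrameModel",
    "SimulationSpec",
    "SyntheticDataset",
    "default_phantom_descriptor",
    "variant_lobe_component",
    "make_phantom",
    "simulate_tilt_series",
    "simulate_frames",
    "simulate_picking_tomogram",
    "make_shell_volume",
]


@dataclass
class SphereComponent:
    """One smooth-sphere component of a phantom: center (voxels, relative to box center)."""

    center: tuple[float, float, float]
    radius: float  # voxels
    amplitude: float = 1.0
    edge: float = 1.0  # soft-edge width, voxels

    def analytic_volume(self) -> float:
        """Closed-form integral of the soft-edged (tanh) sphere profile.

        integral of 0.5*(1 - tanh((r-R)/w)) over R^3 =
        4*pi*(R^3/3 + 2*R*w^2 * pi^2/24) (the x^2 moment of the odd edge
        residual vanishes).
        """
        R, w = self.radius, self.edge
        return self.amplitude * 4.0 * np.pi * (R**3 / 3.0 + 2.0 * R * w**2 * np.pi**2 / 24.0)


def default_phantom_descriptor() -> list[SphereComponent]:
    """An asymmetric multi-sphere composite (no rotational symmetry, so all
    three Euler angles are identifiable)."""
    return [
        SphereComponent((0.0, 0.0, 0.0), 7.0, 1.0),
        SphereComponent((6.0, 2.0, 0.0), 3.0, 1.3),
        SphereComponent((-3.0, 5.0, 3.0), 2.5, 0.9),
        SphereComponent((0.0, -5.0, -4.0), 2.2, 1.5),
    ]


def variant_lobe_component(scale: float = 1.0) -> SphereComponent:
    """The appended lobe distinguishing the second structural variant."""
    return SphereComponent((-5.0 * scale, -3.0 * scale, 4.0 * scale), 3.0 * scale, 1.4)


def scaled_phantom_descriptor(scale: float) -> list[SphereComponent]:
    return [
        SphereComponent(tuple(scale * np.asarray(c.center)), scale * c.radius, c.amplitude)
        for c in default_phantom_descriptor()
    ]


def benchmark_spec(**overrides) -> "SimulationSpec":
    """The standard synthetic benchmark: 64-voxel particle box, 41 tilts
    -60..+60 step 3, SNR 0.5, 50 particles, 2 A/px."""
    kw = dict(
        tomogram_dims=(640, 640, 80),
        pixel_size=2.0,
        betas=np.arange(-60.0, 60.1, 3.0),
        n_particles=50,
        box=64,
        phantom=scaled_phantom_descriptor(2.0),
        snr=0.5,
        rng_seed=42,
    )
    kw.update(overrides)
    return SimulationSpec(**kw)


@dataclass
class DoseModel:
    """Radiation-damage and thickness model applied per tilt.

    Amplitudes are filtered by ``exp(-k^2 * B(e) / 4)`` with ``B(e) = b_rate *
    e`` (Angstrom^2) linear in the accumulated exposure ``e`` (e-/A^2), and
    scaled by ``cos(beta)**thickness_power`` for the tilted-path thickness.
    """

    dose_per_tilt: float = 3.0  # e-/A^2 per exposure
    b_rate: float = 0.6  # A^2 per accumulated e-/A^2
    thickness_power: float = 1.0

    def b_factor(self, exposure_order: int) -> float:
        return self.b_rate * self.dose_per_tilt * exposure_order

    def filter(self, n: int, pixel_size: float, tilt: TiltGeometry) -> np.ndarray:
        _, _, k, _ = freq_grid_2d(n, pixel_size)
        b = self.b_factor(tilt.exposure_order)
        amp = np.cos(np.deg2rad(tilt.beta)) ** self.thickness_power
        return amp * np.exp(-k * k * b / 4.0)


@dataclass
class DeformationModel:
    """Per-region geometric perturbation standing in for beam-induced motion.

    Each region gets a random in-plane shift direction; the shift magnitude
    grows linearly with accumulated exposure up to ``max_shift`` pixels.
    Optional per-region tilt-angle perturbations up to ``max_angle`` degrees
    follow the same exposure ramp.
    """

    grid: tuple[int, int, int] = (2, 2, 1)
    max_shift: float = 4.0  # pixels at the final exposure
    max_angle: float = 0.0  # degrees at the final exposure

    def sample(self, n_tilts: int, exposure_order: np.ndarray, rng) -> np.ndarray:
        G = int(np.prod(self.grid))
        deltas = np.zeros((G, n_tilts, 4))
        ramp = exposure_order / max(n_tilts - 1, 1)
        for g in range(G):
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            amp = rng.uniform(0.5, 1.0) * self.max_shift
            deltas[g, :, 2] = amp * direction[0] * ramp
            deltas[g, :, 3] = amp * direction[1] * ramp
            if self.max_angle > 0:
                deltas[g, :, 0] = rng.uniform(-1, 1) * self.max_angle * ramp
                deltas[g, :, 1] = rng.uniform(-1, 1) * self.max_angle * ramp
        return deltas


@dataclass
class FrameModel:
    """Per-tilt video acquisition: shared drift = linear term + random walk.

    With the default settings each frame is an undamaged shifted copy of
    ``signal/n_frames`` and the frame sum matches the tilt image statistics
    exactly.  ``intra_frame_blur`` adds directional motion blur proportional
    to the within-frame drift step (strongest early, while the stage
    settles) and ``intra_frame_damage`` adds extra B-factor decay with the
    within-tilt accumulated dose (strongest late); together they produce the
    characteristic bell-shaped per-frame score curve of real videos.
    """

    n_frames: int = 8
    drift_sigma: float = 0.3  # random-walk step, px/frame
    drift_linear: float = 0.2  # linear drift magnitude, px/frame
    settle_drift: float = 0.0  # extra initial drift (px/frame) decaying as the stage settles
    settle_tau: float = 2.0  # settle time constant, frames
    intra_frame_blur: float = 0.0  # blur length multiplier on the drift step
    intra_frame_damage: float = 0.0  # extra B per frame index, A^2

    def sample_trajectory(self, rng) -> np.ndarray:
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        f = np.arange(self.n_frames, dtype=float)
        steps = rng.normal(0.0, self.drift_sigma, size=(self.n_frames, 2))
        steps[0] = 0.0
        traj = np.cumsum(steps, axis=0)
        traj += self.drift_linear * direction * f[:, None]
        if self.settle_drift > 0:
            settle = self.settle_drift * self.settle_tau * (1.0 - np.exp(-f / self.settle_tau))
            traj += settle[:, None] * direction
        return traj - traj[0]


def _dose_symmetric_order(betas: np.ndarray) -> np.ndarray:
    """Exposure order: zero tilt first, then alternating signs of growing |beta|."""
    idx = np.lexsort((betas < 0, np.abs(betas)))
    order = np.empty(len(betas), dtype=int)
    order[idx] = np.arange(len(betas))
    return order


@dataclass
class SimulationSpec:
    tomogram_dims: tuple[int, int, int] = (400, 400, 48)
    pixel_size: float = 2.0  # Angstrom
    betas: np.ndarray = field(default_factory=lambda: np.arange(-60.0, 60.1, 3.0))
    alpha: float = 5.0  # tilt-axis angle, degrees
    n_particles: int = 50
    box: int = 32  # particle box, unbinned pixels
    phantom: list[SphereComponent] | None = None
    two_variants: bool = False  # add a second phantom variant (classification tests)
    snr: float = 0.5
    defocus: float = 25000.0  # Angstrom, underfocus positive
    defocus_jitter: float = 500.0  # per-tilt random offset s.d.
    astigmatism: float = 0.0  # df1 - df2
    astig_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    dose: DoseModel | None = field(default_factory=DoseModel)
    deformation: DeformationModel | None = None
    frames: FrameModel | None = None
    min_separation: float | None = None  # voxels; default 0.75 * box
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.box % 2:
            raise ValueError("particle box must be even")


@dataclass
class SyntheticDataset:
    """Everything a round-trip test needs: data plus full ground truth."""

    spec: SimulationSpec
    phantom: np.ndarray
    variant_phantoms: list[np.ndarray]
    tilt_images: np.ndarray  # (T, ny, nx) float32, noisy
    signal_images: np.ndarray  # (T, ny, nx) float32, noise-free
    tilts: list[TiltGeometry]
    tilt_ctfs: list[CTFParams]
    particles: list[ParticlePose]
    class_labels: np.ndarray  # (P,) int, all zero unless two_variants
    region_grid: RegionGrid | None
    true_deltas: np.ndarray | None  # (G, T, 4)
    noise_sigma: float
    frames: np.ndarray | None = None  # (T, F, ny, nx) float32
    frame_trajectories: np.ndarray | None = None  # (T, F, 2) true shifts, px

    @property
    def region_ids(self) -> np.ndarray | None:
        if self.region_grid is None:
            return None
        return self.region_grid.assign([p.pos for p in self.particles])


def make_phantom(
    descriptor: list[SphereComponent], box: int, pixel_size: float = 1.0
) -> np.ndarray:
    """Render a smooth positive density on a zero background, band-limited below Nyquist.

    The soft sphere edges (tanh profile, ~1 voxel) keep the density smooth so
    its spectrum decays well before Nyquist; total integrated density matches
    the analytic sum of component volumes to ~1%.
    """
    if box % 2:
        raise ValueError("box must be even")
    half = box // 2
    for comp in descriptor:
        if np.linalg.norm(comp.center) + comp.radius > half - 2:
            raise ValueError(f"phantom component {comp} does not fit inside box {box}")
    ax = np.arange(box) - half
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((box, box, box))
    for comp in descriptor:
        cx, cy, cz = comp.center
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        vol += comp.amplitude * 0.5 * (1.0 - np.tanh((r - comp.radius) / comp.edge))
    return vol


def _place_particles(spec: SimulationSpec, rng) -> list[ParticlePose]:
    nx, ny, nz = spec.tomogram_dims
    margin = spec.box // 2 + 2
    min_sep = spec.min_separation if spec.min_separation is not None else 0.75 * spec.box
    # keep projected positions separated at every tilt so crops stay clean
    # (sparse picking; dense fields are out of scope for the benchmarks)
    # overlap at the most extreme tilts is tolerated (it is unavoidable in
    # real data because of the cos(beta) footprint compression)
    proj_sep = 0.85 * spec.box
    center = volume_center(spec.tomogram_dims)
    betas = np.asarray(spec.betas, dtype=float)
    betas = betas[np.abs(betas) <= 40.0][::3]
    from .geometry import tilt_matrix

    mats = np.stack([tilt_matrix(spec.alpha, b) for b in betas])
    positions: list[np.ndarray] = []
    proj_xy: list[np.ndarray] = []  # (B, 2) per particle
    tries = 0
    while len(positions) < spec.n_particles:
        tries += 1
        if tries > 500 * spec.n_particles:
            raise RuntimeError(
                "could not place particles with the requested separation; "
                "reduce n_particles or min_separation, or enlarge the tomogram"
            )
        p = np.array(
            [
                rng.uniform(margin, nx - margin),
                rng.uniform(margin, ny - margin),
                rng.uniform(margin, nz - margin),
            ]
        )
        if any(np.linalg.norm(p - q) < min_sep for q in positions):
            continue
        u = (mats @ (p - center))[:, :2]
        if any(np.min(np.linalg.norm(u - v, axis=1)) < proj_sep for v in proj_xy):
            continue
        positions.append(p)
        proj_xy.append(u)
    rots = Rotation.random(spec.n_particles, rng=rng)
    return [
        ParticlePose(i, positions[i], matrix_to_euler(rots[i].as_matrix()))
        for i in range(spec.n_particles)
    ]


def simulate_tilt_series(spec: SimulationSpec, particles=None) -> SyntheticDataset:
    """Generate a full synthetic tilt series with ground-truth tables.

    For each tilt, every particle is projected through the pose-composition
    mapping (including any true per-region deformation), multiplied by its
    per-particle CTF and the dose filter, and summed into the tilt image;
    white Gaussian noise is then added to reach the target SNR measured
    inside the particle boxes.  ``particles`` overrides the random placement
    with an explicit pose list (e.g. grid-aligned orientations for search
    tests).
    """
    rng = np.random.default_rng(spec.rng_seed)
    descriptor = spec.phantom or default_phantom_descriptor()
    phantom = make_phantom(descriptor, spec.box, spec.pixel_size)
    variants = [phantom]
    if spec.two_variants:
        variants = [phantom, make_phantom(descriptor + [variant_lobe_component()], spec.box, spec.pixel_size)]
    projectors = [FourierProjector(v) for v in variants]

    betas = np.asarray(spec.betas, dtype=float)
    T = len(betas)
    order = _dose_symmetric_order(betas)
    tilts = [
        TiltGeometry(t, spec.alpha, betas[t], 0.0, 0.0, int(order[t])) for t in range(T)
    ]
    tilt_ctfs = []
    for _t in range(T):
        df_mean = spec.defocus + rng.normal(0.0, spec.defocus_jitter)
        tilt_ctfs.append(
            CTFParams(
                df_mean + 0.5 * spec.astigmatism,
                df_mean - 0.5 * spec.astigmatism,
                spec.astig_angle,
                spec.voltage,
                spec.cs,
                spec.amplitude_contrast,
            )
        )

    if particles is None:
        particles = _place_particles(spec, rng)
    else:
        particles = list(particles)
    labels = np.zeros(len(particles), dtype=int)
    if spec.two_variants:
        labels = rng.permutation(np.arange(len(particles)) % 2)

    region_grid = None
    true_deltas = None
    region_ids = None
    if spec.deformation is not None:
        region_grid = RegionGrid(*spec.deformation.grid, tuple(spec.tomogram_dims))
        true_deltas = spec.deformation.sample(T, np.array([t.exposure_order for t in tilts]), rng)
        region_ids = region_grid.assign([p.pos for p in particles])

    nx, ny, nz = spec.tomogram_dims
    nb = spec.box
    h = nb // 2
    center = volume_center(spec.tomogram_dims)
    img_c = np.array([nx // 2, ny // 2])
    signal = np.zeros((T, ny, nx))
    box_mask = np.zeros((T, ny, nx), dtype=bool)

    for it, tilt in enumerate(tilts):
        dose_filt = spec.dose.filter(nb, spec.pixel_size, tilt) if spec.dose else 1.0
        for ip, part in enumerate(particles):
            delta = GeometryDelta()
            if true_deltas is not None:
                da, db, dx, dy = true_deltas[region_ids[ip], it]
                delta = GeometryDelta(da, db, dx, dy)
            pose = compose_projection_pose(tilt, part, delta, center)
            u = img_c + np.asarray(pose.shift)
            c_int = np.rint(u).astype(int)
            frac = u - c_int
            x0, y0 = c_int[0] - h, c_int[1] - h
            if x0 < 0 or y0 < 0 or x0 + nb > nx or y0 + nb > ny:
                continue
            ctf = particle_defocus(tilt_ctfs[it], tilt, part.pos, spec.pixel_size, center)
            ctf2d = _ctf_centered(ctf, nb, spec.pixel_size)
            spec2d = projectors[labels[ip]].slice_batch(pose.matrix())
            spec2d = spec2d * ctf2d * dose_filt * shift_phase(nb, frac[0], frac[1])
            signal[it, y0 : y0 + nb, x0 : x0 + nb] += centered_ifft2(spec2d).real
            box_mask[it, y0 : y0 + nb, x0 : x0 + nb] = True

    sig_var = float(np.var(signal[box_mask])) if box_mask.any() else 1.0
    noise_sigma = float(np.sqrt(sig_var / spec.snr))
    images = signal + rng.normal(0.0, noise_sigma, size=signal.shape)

    frames = None
    trajectories = None
    if spec.frames is not None:
        frames, trajectories = simulate_frames(spec, signal, noise_sigma, rng)

    return SyntheticDataset(
        spec=spec,
        phantom=phantom,
        variant_phantoms=variants,
        tilt_images=images.astype(np.float32),
        signal_images=signal.astype(np.float32),
        tilts=tilts,
        tilt_ctfs=tilt_ctfs,
        particles=particles,
        class_labels=labels,
        region_grid=region_grid,
        true_deltas=true_deltas,
        noise_sigma=noise_sigma,
        frames=frames,
        frame_trajectories=trajectories,
    )


def _ctf_centered(params: CTFParams, n: int, pixel_size: float) -> np.ndarray:
    kx, ky, k, az = freq_grid_2d(n, pixel_size)
    return ctf_eval(params, k, az)


def simulate_frames(
    spec: SimulationSpec, signal_images: np.ndarray, noise_sigma: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Split each tilt's signal into drifting video frames plus noise.

    Each frame carries ``signal/n_frames`` shifted by the true per-frame
    trajectory; frame noise is scaled so the frame sum matches the tilt-image
    noise statistics.
    """
    fm = spec.frames
    if fm is None or fm.n_frames < 2:
        raise ValueError("frame simulation requires a FrameModel with >= 2 frames")
    T, ny, nx = signal_images.shape
    F = fm.n_frames
    frames = np.zeros((T, F, ny, nx), dtype=np.float32)
    trajectories = np.zeros((T, F, 2))
    sigma_f = noise_sigma / np.sqrt(F)
    cy = np.fft.fftfreq(ny)[:, None]
    cx = np.fft.fftfreq(nx)[None, :]
    k2 = (cx / spec.pixel_size) ** 2 + (cy / spec.pixel_size) ** 2  # (1/A)^2
    for it in range(T):
        traj = fm.sample_trajectory(rng)
        trajectories[it] = traj
        spec_img = np.fft.fft2(signal_images[it])
        for f in range(F):
            ph = np.exp(-2j * np.pi * (cx * traj[f, 0] + cy * traj[f, 1]))
            filt = 1.0
            if fm.intra_frame_blur > 0:
                step = traj[f] - traj[f - 1] if f > 0 else traj[1] - traj[0]
                filt = filt * np.sinc(fm.intra_frame_blur * (cx * step[0] + cy * step[1]))
            if fm.intra_frame_damage > 0:
                filt = filt * np.exp(-k2 * (fm.intra_frame_damage * f) / 4.0)
            shifted = np.fft.ifft2(spec_img * ph * filt).real
            frames[it, f] = shifted / F + rng.normal(0.0, sigma_f, size=(ny, nx))
    return frames, trajectories


# ---------------------------------------------------------------------------
# Volumes for picking benchmarks
# ---------------------------------------------------------------------------


def simulate_picking_tomogram(
    dims=(96, 96, 48),
    n_particles: int = 30,
    particle_radius: float = 5.0,
    snr: float = 0.5,
    n_contamination: int = 2,
    contamination_radius: float = 9.0,
    rng_seed: int = 0,
):
    """A tomogram of dense (dark) spheres plus high-contrast contamination blobs.

    Density convention is "dense = dark" (negative contrast).  Returns
    ``(volume, true_centers, contamination_centers)``.  SNR is the squared
    particle amplitude over the noise variance.
    """
    rng = np.random.default_rng(rng_seed)
    dims = tuple(dims)
    vol = np.zeros(dims[::-1])  # (z, y, x)
    margin = 2 * particle_radius
    contam = []
    while len(contam) < n_contamination:
        p = np.array([rng.uniform(margin, d - margin) for d in dims])
        if not contam or all(
            np.linalg.norm(p - q) > 3 * contamination_radius for q in contam
        ):
            contam.append(p)
    contam = np.array(contam).reshape(-1, 3)
    # contamination physically displaces particles: keep them clear of it
    clear = contamination_radius + 3.0 * particle_radius
    centers = []
    tries = 0
    while len(centers) < n_particles and tries < 20000:
        tries += 1
        p = np.array([rng.uniform(margin, d - margin) for d in dims])
        if any(np.linalg.norm(p - q) <= clear for q in contam):
            continue
        if all(np.linalg.norm(p - q) > 3.0 * particle_radius for q in centers):
            centers.append(p)
    centers = np.array(centers)

    z, y, x = np.meshgrid(*(np.arange(d) for d in dims[::-1]), indexing="ij")
    for c in centers:
        r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        vol -= 0.5 * (1.0 - np.tanh(r - particle_radius))
    for c in contam:
        r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        vol -= 6.0 * 0.5 * (1.0 - np.tanh(r - contamination_radius))
    sigma = 1.0 / np.sqrt(snr)
    vol += rng.normal(0.0, sigma, size=vol.shape)
    return vol, centers, contam


def make_shell_volume(dims, centers, radii, thickness: float = 2.0, amplitude: float = 1.0):
    """Hollow spherical shells (vesicle/virion stand-ins) on a zero background."""
    z, y, x = np.meshgrid(*(np.arange(d) for d in tuple(dims)[::-1]), indexing="ij")
    vol = np.zeros(tuple(dims)[::-1])
    for c, R in zip(np.atleast_2d(centers), np.atleast_1d(radii)):
        r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        vol += amplitude * np.exp(-((r - R) ** 2) / (2.0 * (thickness / 2.355) ** 2))
    return vol
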