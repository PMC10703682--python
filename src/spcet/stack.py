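"""Per-particle projection crops extracted from tilt images.

Refinement and classification never store free per-projection alignments; they
operate on fixed crops cut from the tilt images around each particle's
predicted projection position, and express all candidate shifts relative to
the crop centers through the pose-composition mapping.  The crops are cut
once (at the current particle positions) and all subsequent sub-pixel motion
is handled by Fourier phase ramps, which keeps scoring cheap and exactly
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    GeometryDelta,
    ParticlePose,
    TiltGeometry,
    compose_projection_pose,
    volume_center,
)
from .projector import centered_fft2, fourier_crop_image

__all__ = ["ProjectionStack", "extract_crops"]


@dataclass
class ProjectionStack:
    """Crops of every (particle, tilt) projection plus the bookkeeping to score them.

    ``offsets[p, t]`` is the crop center minus the tilt-image center, in
    unbinned pixels: a particle whose composed projection shift is ``u`` sits
    at in-crop displacement ``u - offsets[p, t]`` (in unbinned pixels) from
    the crop center.
    """

    crops: np.ndarray  # (P, T, nb, nb) float32
    offsets: np.ndarray  # (P, T, 2) float
    valid: np.ndarray  # (P, T) bool — crop fully inside the tilt image
    tilts: list[TiltGeometry]
    pixel_size: float  # unbinned Angstrom/pixel
    tomogram_dims: tuple[int, int, int]
    binning: int = 1
    _ffts: dict = field(default_factory=dict, repr=False)

    @property
    def n_particles(self) -> int:
        return self.crops.shape[0]

    @property
    def n_tilts(self) -> int:
        return self.crops.shape[1]

    @property
    def box(self) -> int:
        return self.crops.shape[-1]

    @property
    def center(self) -> np.ndarray:
        return volume_center(self.tomogram_dims)

    def crop_ffts(self, p: int) -> np.ndarray:
        """Centered 2D FFTs of all crops of particle ``p`` (cached)."""
        if p not in self._ffts:
            self._ffts[p] = centered_fft2(self.crops[p].astype(float))
        return self._ffts[p]

    def in_crop_shift(self, p: int, shifts: np.ndarray) -> np.ndarray:
        """Convert composed projection shifts (unbinned px) to in-crop binned px."""
        return (np.asarray(shifts) - self.offsets[p]) / self.binning

    def binned(self, factor: int) -> "ProjectionStack":
        """Fourier-crop every projection by ``factor`` (anti-aliased binning)."""
        if factor == 1:
            return self
        crops = np.stack(
            [fourier_crop_image(self.crops[p].astype(float), factor) for p in range(self.n_particles)]
        ).astype(np.float32)
        return ProjectionStack(
            crops=crops,
            offsets=self.offsets,
            valid=self.valid,
            tilts=self.tilts,
            pixel_size=self.pixel_size,
            tomogram_dims=self.tomogram_dims,
            binning=self.binning * factor,
        )


def extract_crops(
    tilt_images: np.ndarray,
    tilts: list[TiltGeometry],
    particles: list[ParticlePose],
    box: int,
    tomogram_dims,
    pixel_size: float,
    region_deltas=None,
    region_ids=None,
) -> ProjectionStack:
    """Cut a ``box``-sized crop around every particle's predicted projection.

    Crop centers are the rounded composed projection positions; particles whose
    crop would fall outside a tilt image are marked invalid for that tilt.
    """
    T, ny, nx = tilt_images.shape
    P = len(particles)
    center = volume_center(tomogram_dims)
    img_c = np.array([nx // 2, ny // 2])
    crops = np.zeros((P, T, box, box), dtype=np.float32)
    offsets = np.zeros((P, T, 2))
    valid = np.zeros((P, T), dtype=bool)
    h = box // 2
    for ip, part in enumerate(particles):
        for it, tilt in enumerate(tilts):
            delta = GeometryDelta()
            if region_deltas is not None and region_ids is not None:
                da, db, dx, dy = region_deltas[region_ids[ip], it]
                delta = GeometryDelta(da, db, dx, dy)
            pose = compose_projection_pose(tilt, part, delta, center)
            c = np.rint(img_c + np.asarray(pose.shift)).astype(int)
            x0, y0 = c[0] - h, c[1] - h
            if x0 < 0 or y0 < 0 or x0 + box > nx or y0 + box > ny:
                continue
            crops[ip, it] = tilt_images[it, y0 : y0 + box, x0 : x0 + box]
            offsets[ip, it] = c - img_c
            valid[ip, it] = True
    return ProjectionStack(
        crops=crops,
        offsets=offsets,
        valid=valid,
        tilts=list(tilts),
        pixel_size=pixel_size,
        tomogram_dims=tuple(tomogram_dims),
    )
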