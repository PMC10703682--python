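"""Fourier central-slice projection of a 3D reference volume.

By the projection-slice theorem, the 2D Fourier transform of a parallel-beam
projection of a volume equals a central plane of the volume's 3D transform.
All projection operators in this package (tilt-series simulation, score
evaluation during refinement, and the adjoint used for reconstruction) go
through this module so the forward model is exactly self-consistent.

Arrays are indexed ``[z, y, x]``; rotation matrices act on ``(x, y, z)``
coordinate vectors.  Fourier data is kept in *centered* layout (zero frequency
at index ``N//2``); :func:`centered_fft2` / :func:`centered_ifft2` convert to
and from image space.  A rotation ``Q`` maps reference-frame coordinates to
the lab frame; the projection along lab z then samples the reference
transform at ``Q^T (kx, ky, 0)``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "FourierProjector",
    "centered_fft2",
    "centered_ifft2",
    "shift_phase",
    "freq_grid_2d",
    "band_mask",
    "fourier_crop_image",
    "fourier_crop_volume",
]


def centered_fft2(img: np.ndarray) -> np.ndarray:
    """2D FFT with both origin conventions centered (image center -> N//2)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), axes=(-2, -1)), axes=(-2, -1))


def centered_ifft2(spec: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec, axes=(-2, -1)), axes=(-2, -1)), axes=(-2, -1))


def _centered_coords(n: int) -> np.ndarray:
    # integer frequency indices -n/2 .. n/2-1 (even n)
    return np.arange(n, dtype=float) - n // 2


def freq_grid_2d(n: int, pixel_size: float = 1.0):
    """Centered (ky, kx) grids in 1/Angstrom plus radius and azimuth arrays."""
    c = _centered_coords(n) / (n * pixel_size)
    ky = c[:, None]
    kx = c[None, :]
    return kx, ky, np.hypot(kx, ky), np.arctan2(np.broadcast_to(ky, (n, n)), np.broadcast_to(kx, (n, n)))


def band_mask(n: int, pixel_size: float, band: tuple[float, float]) -> np.ndarray:
    """Boolean annulus for a resolution band ``(low_res, high_res)`` in Angstrom.

    ``low_res > high_res`` (e.g. ``(40, 8)``); frequencies strictly above zero
    and below Nyquist are kept, so the mask is offset- and scale-insensitive
    when used for normalized correlation.
    """
    lo_res, hi_res = band
    if hi_res <= 2.0 * pixel_size * (1.0 - 1e-9):
        hi_res = 2.0 * pixel_size
    _, _, r, _ = freq_grid_2d(n, pixel_size)
    mask = (r >= 1.0 / lo_res) & (r <= 1.0 / hi_res) & (r > 0)
    if not mask.any():
        raise ValueError(f"empty frequency band {band} for box {n} at {pixel_size} A/px")
    return mask


def shift_phase(n: int, shift_x: float, shift_y: float) -> np.ndarray:
    """Phase ramp that translates an image by ``(shift_x, shift_y)`` pixels."""
    c = _centered_coords(n) / n
    return np.exp(-2j * np.pi * (c[None, :] * shift_x + c[:, None] * shift_y))


def fourier_crop_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Bin an image by cropping its centered Fourier transform (anti-aliased)."""
    if factor == 1:
        return np.asarray(img, dtype=float)
    n = img.shape[-1]
    m = n // factor
    lo = n // 2 - m // 2
    spec = centered_fft2(img)[..., lo : lo + m, lo : lo + m]
    return centered_ifft2(spec).real / factor**2


def fourier_crop_volume(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(vol, dtype=float)
    n = vol.shape[0]
    m = n // factor
    lo = n // 2 - m // 2
    spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))
    spec = spec[lo : lo + m, lo : lo + m, lo : lo + m]
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec))).real / factor**3


class FourierProjector:
    """Projects a cubic reference volume at arbitrary orientations.

    The volume transform is computed once; each projection is a trilinear
    central-slice lookup plus a 2D inverse transform, which makes scoring many
    candidate poses cheap.
    """

    def __init__(self, volume: np.ndarray):
        volume = np.asarray(volume, dtype=float)
        if volume.ndim != 3 or len(set(volume.shape)) != 1:
            raise ValueError("reference volume must be a cube")
        n = volume.shape[0]
        if n % 2:
            raise ValueError("box size must be even")
        self.n = n
        F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(volume)))
        # drop the asymmetric Nyquist faces so slices of a real volume stay Hermitian
        F[0, :, :] = 0
        F[:, 0, :] = 0
        F[:, :, 0] = 0
        self._F = np.ascontiguousarray(F)
        k = _centered_coords(n)
        self._KX = k[None, None, :]
        self._KY = k[None, :, None]

    def slice_batch(self, Q: np.ndarray) -> np.ndarray:
        """Centered Fourier slices for a stack of orientations ``Q`` (B, 3, 3).

        Returns a complex array (B, n, n): the transform of the projection of
        the reference rotated by each ``Q[b]``, before any shift or CTF.
        """
        Q = np.asarray(Q, dtype=float)
        squeeze = Q.ndim == 2
        if squeeze:
            Q = Q[None]
        B = Q.shape[0]
        n = self.n
        # sample points Q^T (kx, ky, 0) = kx * row0(Q) + ky * row1(Q)
        r0 = Q[:, 0, :][:, None, None, :]
        r1 = Q[:, 1, :][:, None, None, :]
        pts = self._KX[..., None] * r0 + self._KY[..., None] * r1  # (B, n, n, 3) -> (qx,qy,qz)
        c = n // 2
        coords = np.empty((3, B, n, n))
        coords[0] = pts[..., 2] + c  # z index
        coords[1] = pts[..., 1] + c  # y index
        coords[2] = pts[..., 0] + c  # x index
        out = map_coordinates(self._F, coords.reshape(3, -1), order=1, mode="constant", cval=0.0)
        out = out.reshape(B, n, n)
        return out[0] if squeeze else out

    def slice_points(self, Q: np.ndarray, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
        """Sample the central slices only at the given integer frequency coords.

        ``kx``, ``ky`` are centered integer frequencies (m,); ``Q`` is (B, 3, 3)
        or (3, 3).  Returns complex (B, m) — the hot path for band-limited
        score evaluation, which never needs the full plane.
        """
        Q = np.asarray(Q, dtype=float)
        squeeze = Q.ndim == 2
        if squeeze:
            Q = Q[None]
        B = Q.shape[0]
        m = kx.size
        r0 = Q[:, 0, :][:, None, :]
        r1 = Q[:, 1, :][:, None, :]
        pts = kx[None, :, None] * r0 + ky[None, :, None] * r1  # (B, m, 3)
        c = self.n // 2
        coords = np.empty((3, B, m))
        coords[0] = pts[..., 2] + c
        coords[1] = pts[..., 1] + c
        coords[2] = pts[..., 0] + c
        out = map_coordinates(self._F, coords.reshape(3, -1), order=1, mode="constant", cval=0.0)
        out = out.reshape(B, m)
        return out[0] if squeeze else out

    def project(self, Q: np.ndarray, shift=(0.0, 0.0)) -> np.ndarray:
        """Real-space projection image at orientation ``Q``, shifted by ``shift`` pixels."""
        spec = self.slice_batch(Q) * shift_phase(self.n, *shift)
        return centered_ifft2(spec).real

    def project_batch(self, Q: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        spec = self.slice_batch(Q)
        shifts = np.asarray(shifts, dtype=float)
        c = _centered_coords(self.n) / self.n
        ph = np.exp(
            -2j
            * np.pi
            * (
                c[None, None, :] * shifts[:, 0, None, None]
                + c[None, :, None] * shifts[:, 1, None, None]
            )
        )
        return centered_ifft2(spec * ph).real
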