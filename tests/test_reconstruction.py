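"""Fourier-inversion reconstruction, merging, FSC and exposure weights."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spcet.projector import FourierProjector
from spcet.reconstruction import (
    PartialReconstruction,
    exposure_weights,
    fsc,
    fsc_resolution,
    insert_projections,
    merge_bundles,
    normalize_map,
    reconstruct,
)
from spcet.stack import extract_crops


class TestInsertAndNormalize:
    def test_full_coverage_round_trip(self):
        """Projections covering the sphere reconstruct the phantom (corr > 0.99)."""
        from spcet.simulator import default_phantom_descriptor, make_phantom

        vol = make_phantom(default_phantom_descriptor(), 32)
        pr = FourierProjector(vol)
        rng = np.random.default_rng(0)
        Qs = Rotation.random(400, rng=rng).as_matrix()
        imgs = np.stack([pr.project(Q) for Q in Qs])
        part = PartialReconstruction.empty(32)
        insert_projections(part, imgs, Qs)
        rec = normalize_map(part, wiener_frac=1e-4)
        cc = np.corrcoef(rec.ravel(), vol.ravel())[0, 1]
        assert cc > 0.99

    def test_missing_wedge_empty(self):
        """With co-oriented particles, the +/-60 deg scheme leaves an empty
        wedge in the reference-frame Fourier accumulation."""
        from spcet.geometry import ParticlePose
        from spcet.simulator import SimulationSpec, simulate_tilt_series

        spec = SimulationSpec(
            n_particles=4, betas=np.arange(-60, 60.1, 10.0), snr=1e9, rng_seed=9, dose=None
        )
        particles = [
            ParticlePose(i, (80.0 + 90.0 * i, 200.0, 24.0), (0.0, 0.0, 0.0))
            for i in range(4)
        ]
        ds = simulate_tilt_series(spec, particles=particles)
        stack = extract_crops(
            ds.tilt_images, ds.tilts, particles, spec.box, spec.tomogram_dims, spec.pixel_size
        )
        _, _, _, combined = reconstruct(stack, particles, ds.tilt_ctfs)
        n = spec.box
        c = n // 2
        ax = np.arange(n) - c
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(x * x + y * y + z * z)
        # a voxel is sampled only within the trilinear support (~1 voxel) of
        # an inserted central-slice plane (normal = third row of the tilt
        # rotation for identity particle orientations)
        pts = np.stack([x, y, z], axis=-1).reshape(-1, 3).astype(float)
        min_dist = np.full(pts.shape[0], np.inf)
        for t in ds.tilts:
            min_dist = np.minimum(min_dist, np.abs(pts @ t.matrix()[2]))
        wedge = (min_dist.reshape(x.shape) > 2.0) & (r > 4) & (r < c - 2)
        assert wedge.sum() > 100  # the tilt range does leave a wedge
        assert np.abs(combined.num[wedge]).max() <= 1e-6 * np.abs(combined.num).max()

    def test_linearity_of_merge(self, noiseless_ds):
        ds = noiseless_ds
        spec = ds.spec
        stack = extract_crops(
            ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
        )
        _, _, _, all_at_once = reconstruct(stack, ds.particles, ds.tilt_ctfs)
        parts = []
        for p in range(stack.n_particles):
            _, _, _, c = reconstruct(stack, ds.particles, ds.tilt_ctfs, particle_subset=[p])
            parts.append(c)
        merged = merge_bundles(parts)
        assert np.allclose(merged.num, all_at_once.num, atol=1e-10 * np.abs(all_at_once.num).max())
        assert np.allclose(merged.den, all_at_once.den, atol=1e-10 * all_at_once.den.max())


class TestMergeBundles:
    def _random_partials(self, k, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(k):
            p = PartialReconstruction.empty(16)
            p.num += rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
            p.den += rng.uniform(size=(16, 16, 16))
            out.append(p)
        return out

    def test_single_partial_identity(self):
        (p,) = self._random_partials(1)
        merged = merge_bundles([p])
        assert np.array_equal(normalize_map(merged), normalize_map(p))

    def test_permutation_invariance_bitwise(self):
        parts = self._random_partials(5, seed=1)
        rng = np.random.default_rng(2)
        maps = []
        for _ in range(3):
            order = rng.permutation(5)
            merged = merge_bundles([parts[i] for i in order])
            maps.append(normalize_map(merged))
        assert np.array_equal(maps[0], maps[1])
        assert np.array_equal(maps[0], maps[2])

    def test_mismatched_boxes_rejected(self):
        a = PartialReconstruction.empty(16)
        b = PartialReconstruction.empty(32)
        with pytest.raises(ValueError):
            merge_bundles([a, b])


class TestFsc:
    def test_identical_maps_unity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(32, 32, 32))
        freqs, curve = fsc(vol, vol, 2.0)
        assert np.allclose(curve, 1.0)
        assert fsc_resolution(freqs, curve) == pytest.approx(1.0 / freqs[-1])

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        freqs, curve = fsc(a, b, 2.0)
        n = 32
        c = n // 2
        ax = np.arange(n) - c
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        shell = np.minimum(np.rint(np.sqrt(x * x + y * y + z * z)).astype(int), c)
        sizes = np.bincount(shell.ravel(), minlength=c + 1)[1:]
        ok = np.abs(curve) < 3.0 / np.sqrt(sizes)
        assert ok.mean() >= 0.9

    def test_snr_relation(self):
        """FSC between two noisy copies follows SNR / (1 + SNR) per shell."""
        rng = np.random.default_rng(2)
        from spcet.simulator import default_phantom_descriptor, make_phantom

        vol = make_phantom(default_phantom_descriptor(), 32)
        snr_target = 2.0
        sigma = np.sqrt(np.var(vol) / snr_target)
        a = vol + rng.normal(0, sigma, vol.shape)
        b = vol + rng.normal(0, sigma, vol.shape)
        freqs, curve = fsc(a, b, 2.0)
        # per-shell spectral SNR of the phantom against flat noise
        F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))
        n, c = 32, 16
        ax = np.arange(n) - c
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        shell = np.minimum(np.rint(np.sqrt(x * x + y * y + z * z)).astype(int), c)
        p_sig = np.bincount(shell.ravel(), weights=(np.abs(F) ** 2).ravel(), minlength=c + 1)
        counts = np.bincount(shell.ravel(), minlength=c + 1)
        noise_power_per_coeff = sigma**2 * n**3
        snr_shell = (p_sig / counts) / noise_power_per_coeff
        expected = snr_shell / (1.0 + snr_shell)
        sel = counts[1:] > 50
        resid = np.abs(curve[sel] - expected[1:][sel])
        sampling = 3.0 / np.sqrt(counts[1:][sel])
        assert (resid < np.maximum(0.1, 3 * sampling)).mean() > 0.8


class TestExposureWeights:
    def test_equal_scores_uniform(self):
        k = np.linspace(0, 0.25, 32)
        w = exposure_weights(np.full(6, 0.3), k)
        assert np.allclose(w, 1.0 / 6)

    def test_normalized_at_every_frequency(self):
        rng = np.random.default_rng(0)
        k = np.linspace(0, 0.25, 32)
        w = exposure_weights(rng.uniform(0.1, 0.5, 8), k)
        assert np.allclose(w.sum(axis=0), 1.0)

    def test_monotone_in_score(self):
        k = np.linspace(0, 0.25, 64)
        w = exposure_weights([0.4, 0.2], k)
        assert np.all(w[0] >= w[1] - 1e-12)
        assert w[0, -1] > w[1, -1] + 1e-6  # strict at high frequency

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            exposure_weights([0.2, np.nan], np.linspace(0, 0.2, 8))
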