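# spcet

Constrained single-particle refinement for cryo-electron tomography
(SP-CET), built for desk-scale experimentation with full ground truth.

In a tilt series every particle is imaged T times under a known acquisition
geometry, but each 2D projection is far too noisy to align on its own. The
central idea implemented here is to never give projections free alignment
parameters: the five 2D pose parameters of projection *i* follow from the
tilt geometry (tilt-axis angle α, tilt angle β, image shifts) and the
particle's single rigid transformation,

    [x_i, y_i, θ_i, φ_i, ψ_i] = g(α, β, shifts; θ, φ, ψ, x, y, z),

so refinement optimizes 6 parameters per particle instead of 5T. Around
this constraint the package provides:

* **simulator** — synthetic tilt series with known ground truth: phantom
  particles, CTF, dose-dependent damage, per-region deformation, video
  frames with drift;
* **picking** — contamination masking, size-based 3D picking, spherical
  surface detection with outward normals, score/distance cleaning;
* **ctf** — CTF evaluation, per-tilt estimation from Thon rings,
  depth-dependent per-particle defocus, and region-based CTF refinement
  (maximizing the summed matching score D over a region's mean defocus);
* **refinement** — the band-limited correlation score d, exhaustive
  constrained search (optionally restricted by surface normals), 6-DOF
  fully constrained refinement, and region-based geometry refinement that
  models beam-induced deformation;
* **frames** — per-particle video-frame trajectories with
  temporal/spatial regularization and score-driven exposure weighting;
* **classification** — constrained K-class EM in which all projections of
  a particle share one class distribution (Gaussian tilt weighting, s.d.
  6°, global score statistics);
* **reconstruction** — direct Fourier inversion with CTF weighting,
  order-invariant bundle merging, FSC with 0.143 resolution readout;
* **io** — MRC2014 (mode 2), STAR interchange, plain-text metadata
  tables, and a bundle driver whose per-projection intermediates live only
  on scratch.

Because partial reconstructions merge by summation, tilt series can be
processed in bundles whose intermediates are deleted on completion — the
storage this avoids is what `spcet estimate-storage` quantifies (a
12,000-particle dataset at box 384 would otherwise cost 2.5 TB of
sub-volumes or a 270 GB stack of 492,000 extracted projections).

## Worked example

Simulate a 21-tilt series of 10 particles at SNR 0.5, perturb the true
poses by 5° / 3 voxels, and refine them back under the constraint:

```python
import numpy as np
from spcet import (SimulationSpec, simulate_tilt_series, extract_crops,
                   ScoreModel, SearchLimits, refine_fully_constrained,
                   euler_to_matrix, matrix_to_euler, ParticlePose)
from scipy.spatial.transform import Rotation

spec = SimulationSpec(n_particles=10, betas=np.arange(-60, 60.1, 6.0),
                      snr=0.5, rng_seed=7)
ds = simulate_tilt_series(spec)
stack = extract_crops(ds.tilt_images, ds.tilts, ds.particles,
                      spec.box, spec.tomogram_dims, spec.pixel_size)
model = ScoreModel(ds.phantom, stack, band=(100.0, 6.0),
                   tilt_ctfs=ds.tilt_ctfs)

rng = np.random.default_rng(1)
perturbed = []
for p in ds.particles:
    axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(5.0) * axis).as_matrix() @ euler_to_matrix(p.angles)
    dp = rng.normal(size=3); dp *= 3.0 / np.linalg.norm(dp)
    perturbed.append(ParticlePose(p.particle_id, p.pos + dp, matrix_to_euler(R)))

refined, info = refine_fully_constrained(model, perturbed,
                                         SearchLimits(angle=8.0, shift=5.0))

def ang_err(a, b):
    c = (np.trace(euler_to_matrix(a.angles).T @ euler_to_matrix(b.angles)) - 1) / 2
    return np.degrees(np.arccos(np.clip(c, -1, 1)))

print("median angular error: %.2f deg" %
      np.median([ang_err(t, r) for t, r in zip(ds.particles, refined)]))
print("median shift error:   %.2f voxels" %
      np.median([np.linalg.norm(t.pos - r.pos) for t, r in zip(ds.particles, refined)]))
```

prints

```
median angular error: 1.43 deg
median shift error:   0.08 voxels
```

— the 5° / 3-voxel perturbation collapses to degree-scale, sub-tenth-voxel
residuals because all 21 projections of each particle vote on its six
parameters jointly. (At the standard benchmark scale — a 64-voxel box and
41 tilts — the median angular residual drops to ~0.3°.)

The same pipeline is scriptable from the shell:

```bash
spcet simulate proj/ --seed 7 --particles 10 --snr 0.5
spcet refine proj/ --angle-limit 8 --shift-limit 5
spcet reconstruct proj/
spcet fsc proj/half_0.mrc proj/half_1.mrc
spcet estimate-storage --particles 12000 --tilts 41 --box 384
```

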