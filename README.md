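# lopdwi

Voxel-wise denoising of high angular resolution diffusion MRI (HARDI) by
**low-pass filtering in the gradient direction domain** ("lop-DWI"), for
researchers who design diffusion acquisitions or study crossing-fiber
reconstruction.

In HARDI, each volume measures the normalized diffusion signal
`s_n = E(b, d_n) / E_0` for one gradient direction `d_n` on the unit
sphere.  If the directions are acquired along a continuous spherical
spiral, the per-voxel samples `s = (s_1, …, s_N)`, ordered by
acquisition, form a smooth pseudo-periodic 1D signal whose fiber
information concentrates in the low-frequency Fourier bins while thermal
(Rician) noise spreads over all bins.  The lop-DWI filter:

1. detrends `s` by its least-squares line in the sample index,
2. zeroes every DFT bin with frequency index ≥ 11 (retaining 21 of 82
   complex bins, ≈ 25% of the spectrum for an 82-direction scheme),
3. re-adds the trend and clips negative samples to zero.

The package provides the full validation loop around that filter:

- **`lopdwi.sampling`** — gradient schemes: the analytically exact
  equal-arc-length spherical spiral (antipodally symmetric; a 164-point
  sphere reduces to 82 hemisphere directions), an uneven 20°-step
  periodic spiral, and electrostatic-repulsion schemes, with uniformity
  diagnostics and FSL bval/bvec I/O.
- **`lopdwi.phantom`** — a crossing-fiber digital phantom: thin straight
  bundles in a spherical domain, a stick + zeppelin two-compartment
  white-matter signal model, and Rician noise at prescribed SNR.
- **`lopdwi.gdd_filter`** — the filter itself, as an idempotent
  projection onto {trend + low-frequency Fourier modes}, applied voxel-wise.
- **`lopdwi.recon`** — regularized analytic Q-ball imaging: order-8 real
  symmetric spherical harmonics, Laplace–Beltrami regularization
  (λ = 0.006), the Funk–Radon transform `c'_{lm} = 2π P_l(0) c_{lm}`, peak
  extraction on a subdivided icosahedron (≤ 3 peaks per voxel), and a
  log-linear DTI fit for FA-based masking.
- **`lopdwi.evaluation`** — MSE against ground truth, angular error
  `(180/π)·arccos|p_gt · p_est|` with greedy one-to-one peak matching,
  fiber-count success/over/under rates, median-Otsu SNR estimation, and
  paired t-tests.
- **`lopdwi.io` / `lopdwi.cli`** — NIfTI + gradient-table I/O, dataset
  concatenation, and the `lopdwi` command line (`scheme`, `simulate`,
  `denoise`, `recon`, `dti`, `evaluate`, `concat`) with JSON manifests.

## Worked example

```python
import numpy as np
from lopdwi import generate_exact_spiral, to_hemisphere, uniformity_metrics
from lopdwi import phantom
from lopdwi.gdd_filter import denoise_volume
from lopdwi.evaluation import mse_map, paired_ttest, fiber_count_rates
from lopdwi.recon import qball_pipeline

scheme = to_hemisphere(generate_exact_spiral(164)).with_bvalue(3000.0)
rep = uniformity_metrics(scheme)
print(f"scheme: {scheme.n} directions, min pairwise angle "
      f"{rep.min_pairwise_angle:.1f} deg, max spiral step {rep.max_consecutive_step:.1f} deg")

gt = phantom.build_ground_truth(phantom.default_test_spec(), seed=0)
clean = phantom.simulate_signal(gt, scheme)
noisy = phantom.add_rician_noise(clean, snr=20.0, seed=42)
denoised = denoise_volume(noisy)

mse_raw = mse_map(noisy, clean, gt.mask)
mse_lop = mse_map(denoised, clean, gt.mask)
t = paired_ttest(mse_raw.per_voxel[gt.mask], mse_lop.per_voxel[gt.mask])
print(f"MSE raw {mse_raw.mean:.2e} -> lop {mse_lop.mean:.2e} "
      f"(paired t={t.t:.1f}, p={t.p:.1e}, n={mse_raw.n_voxels})")

fiber = gt.fiber_mask().reshape(-1)
counts_gt = gt.fiber_counts().reshape(-1)[fiber]
for name, vol in (("raw", noisy), ("lop", denoised)):
    sig = vol.weighted.reshape(-1, scheme.n)[fiber]
    _, peaks = qball_pipeline(sig, scheme.directions)
    r = fiber_count_rates(peaks.counts, counts_gt)
    print(f"{name}-QBI: success {r.success:.1f}%  over {r.over_estimation:.1f}%  "
          f"under {r.under_estimation:.1f}%  ({r.n_voxels} fiber voxels)")
```

prints

```
scheme: 82 directions, min pairwise angle 8.1 deg, max spiral step 15.6 deg
MSE raw 4.44e-03 -> lop 4.24e-03 (paired t=3.7, p=2.1e-04, n=1736)
raw-QBI: success 71.1%  over 27.1%  under 1.8%  (388 fiber voxels)
lop-QBI: success 87.1%  over 8.5%  under 4.4%  (388 fiber voxels)
```

At b = 3000 s/mm² and SNR 20, filtering lowers the signal error against
the noise-free ground truth and — the method's main payoff — suppresses
spurious ODF peaks: the fiber-count success rate rises by 16 points
because the over-estimation rate collapses from 27% to 8%, at the cost
of a small increase in under-estimation.  The same trade-offs across the
whole SNR range are quantified in `docs/methods.md`.

The same pipeline is available from the shell:

```sh
lopdwi scheme --kind exact-spiral --n 164 --bvalue 3000 --out spiral
lopdwi simulate --scheme spiral.scheme --b 3000 --snr 20 --seed 42 --out sim
lopdwi denoise --in sim.nii.gz --bval sim.bval --bvec sim.bvec \
               --order spiral.scheme --out sim_lop.nii.gz
```

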