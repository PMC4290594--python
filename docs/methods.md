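# Methods

## Signal model and filtering premise

Diffusion-weighted MR measures, per voxel and gradient direction `d_n`,
the normalized signal `s_n = E(b, d_n)/E_0` with diffusion weighting
`b = γ² G² δ² (Δ − δ/3)` (γ gyromagnetic ratio, G gradient strength,
δ pulse length, Δ diffusion time).  Because `E(b, d) = E(b, −d)`, the
signal is a smooth antipodally symmetric function on the sphere, with
angular content essentially band-limited to low even spherical-harmonic
degrees (the b-value sets how much energy sits at degrees 4–8).

If the gradient directions are ordered along a continuous spherical
spiral, `s_n` becomes a smooth, pseudo-periodic 1D sequence.  Its
Fourier spectrum concentrates at low bins: the slow pole-to-equator
sweep contributes a trend plus very low frequencies, and the azimuthal
anisotropy of degree-`l`, order-`m` harmonics appears near bin
`≈ m · N · h / (2π sin θ)` (h the arc step).  Noise, by contrast, is
white across all bins.  The lop filter exploits this separation.

## The spiral scheme

`generate_exact_spiral(n_total, turns)` places `n_total/2` points at
exactly equal arc-length intervals along `φ = c·θ` (`c = 2·turns`) on
the upper hemisphere, computing the arc length
`s(θ) = ∫₀^θ √(1 + c² sin² t) dt` by adaptive quadrature and inverting
it with Brent root-finding, then appends the antipodes in reverse order.
The full sequence runs continuously from the north to the south pole and
is exactly antipodally symmetric, so hemisphere reduction
(`to_hemisphere`: flip z < 0 points, collapse duplicate axes, keep the
earlier acquisition index) returns exactly `n_total/2` directions that
remain ordered along the spiral.

`turns = "auto"` uses `round(√(n_total·π)/2)` (11 turns for 164 points),
which equates the spacing along the spiral with the spacing between
adjacent turns and yields near-uniform density: for the 82-direction
hemisphere the antipodally symmetrized Coulomb energy is within 0.2% of
an electrostatic-repulsion optimum at the same count.

There is a genuine tension in this design.  Lowering the azimuthal rate
(fewer turns) compresses the signal's azimuthal harmonics into the
retained low-pass band — at 6 turns the mean out-of-band signal energy
drops from ~11%/23% (b = 1000/3000) to ~3%/4% — but the resulting
azimuthal gaps de-uniformize the scheme and make the filtered,
spiral-correlated noise alias into spurious ODF structure, reversing
the reconstruction benefit at b = 3000.  We keep the uniform
(density-matched) rate: the even distribution is what makes the
reconstruction improvements real, and the residual signal truncation is
acknowledged below as the filter's bias.

## The lop filter

`lop_denoise` projects each direction-ordered voxel signal onto
span{1, n, cos/sin modes of frequency < cutoff}.  One pass of
"detrend → zero bins ≥ cutoff → retrend" is not quite idempotent
(the low-passed residual regains a small slope component); the
projection is that operation iterated to convergence and is exactly
idempotent, linear, and energy-non-increasing on the detrended part.
Negative outputs are clipped to zero by default (magnitude MR data);
clipping and detrending are configurable.

The cutoff counts nonnegative-frequency bins including DC.  The default
11 retains 21 of 82 complex bins (≈ 25% of the spectrum).  Filtering is
defined only for spiral-ordered schemes; `denoise_volume` refuses
unordered (e.g. electrostatic) schemes rather than invent a re-ordering.
b0 volumes pass through untouched.

## Digital phantom

The synthetic-data generator rasterizes straight tubular bundles onto a
voxel grid inside a spherical domain (background outside is zero
signal).  Per voxel, each bundle contributes its centerline tangent as a
fiber direction and a volume fraction from 3³ sub-voxel occupancy
sampling; fractions are normalized to sum ≤ 1, at most three fibers are
kept, and the remainder diffuses isotropically.  Signal per fiber is
stick + zeppelin:

    E/E0 = Σᵢ fᵢ [ν e^(−b λ∥ (d·uᵢ)²) + (1−ν) e^(−b(λ⊥ + (λ∥−λ⊥)(d·uᵢ)²))]
           + (1 − Σ fᵢ) e^(−b D_iso)

with defaults ν = 0.4, λ∥ = 1.7×10⁻³, λ⊥ = 0.3×10⁻³,
D_iso = 3.0×10⁻³ mm²/s — standard white-matter literature values.
Rician noise at SNR `q` replaces each sample `s` by
`√((s+n₁)² + n₂²)`, `n₁,n₂ ~ N(0, (S0/q)²)` with S0 = 1 (the
unweighted signal) as the SNR reference.

The **default study phantom** is a 16³ grid (1 mm voxels, domain radius
7.5 mm) with three thin bundles (radius 1.5 mm) through the center:
along x, along z (90° crossing) and in-plane at 60° to x / 90° to z.
Design rationale:

- *Sparsity.*  Thin tubes keep the white-matter fill at ~22% of domain
  voxels (388 fiber voxels of 1736), as in brain-like phantoms; the MSE
  summary is then not dominated by the filter's behavior on the few
  strongly anisotropic voxels.
- *Resolvable crossings.*  Noise-free probes show the regularized
  Q-ball pipeline resolves only ~90° crossings at b = 1000 s/mm² and
  ≥ 60° at b = 3000, so the orthogonal pairs keep fiber-count errors
  noise-driven rather than resolution-driven.
- *A low-angle region.*  The 60° pair (~4% of fiber voxels) reproduces
  the regime where under-estimation at high SNR originates from
  crossings below the reconstruction's angular resolution.

Ground-truth fiber counting ignores fibers occupying less than a
quarter of a voxel (`min_fraction = 0.25`): a sub-quarter compartment
contributes too little signal to be a fair reconstruction target.

A 27-bundle configuration of random chords in a larger spherical domain
is available (`spherical_27_bundle_spec`) but not used by the tests.

What the phantom does **not** emulate: curved bundles, restricted
(non-Gaussian) intra-axonal diffusion, spin exchange between
compartments, T2/TE effects, spatially correlated physiological noise,
motion and eddy-current distortions.  Passing tests therefore show that
the filter and reconstruction behave as designed under the stated noise
model — not that the same effect sizes transfer to scanner data.

## Reconstruction

Signals are fit in the real symmetric (even-degree) SH basis of order 8
(45 coefficients; convention: θ = arccos z, φ = atan2(y, x); m < 0 →
√2·Re Y, m = 0 → Y, m > 0 → √2·Im Y) by Laplace–Beltrami regularized
least squares, `c = (BᵀB + λ diag(l²(l+1)²))⁻¹ Bᵀ s`, λ = 0.006.  The
ODF follows from the analytic Funk–Radon transform,
`c'_{lm} = 2π P_l(0) c_{lm}`.  Peaks are strict local maxima of the
min-max-normalized ODF on a 4-times-subdivided icosahedron (2562
vertices, ~2° quantization; the coarser 642-vertex sphere is available),
thresholded at 0.1 of the normalized range, greedily selected with a
25° minimum axis separation and capped at three per voxel.  The
relative threshold, minimum separation, peak cap and tessellation are
all configuration.  A constant ODF yields zero peaks by construction.

The DTI fit is ordinary log-linear least squares with signals clamped to
a small epsilon; FA uses the standard normalized eigenvalue-variance
formula.

## Evaluation

- **MSE**: per voxel, mean over directions of the squared difference to
  the noise-free signal; summarized over non-background voxels.
- **Angular error**: `(180/π) arccos |p_gt·p_est|` per ground-truth
  fiber, estimated peaks matched greedily one-to-one by smallest axis
  angle; a voxel's value is the mean over its matched fibers.  Voxels
  with no estimated peak are excluded and counted separately (they
  appear in the under-estimation rate instead).  Note this metric
  rewards pipelines that emit many spurious peaks — the nearest of many
  peaks is close by chance — so it is read together with the count
  rates.
- **Count rates**: success/over/under = estimated count =, >, < true
  count, as percentages of fiber-containing voxels (they sum to 100).
- **SNR**: per direction, ROI mean divided by background SD; masks from
  a median-Otsu split with one-voxel erosion of the background.
- **Paired t-test**: two-sided on per-voxel differences; zero-variance
  differences are flagged rather than given a p-value.

## Study conditions and observed behavior

The phantom study (`lopdwi.study.run_phantom_study`, also driven by
`scripts/acceptance.py`) uses the 82-direction exact-spiral hemisphere,
b ∈ {1000, 3000} s/mm², SNR ∈ {10, 20, 30, 50, 100, 150}, one noise
realization per dataset derived from the global seed, and both the raw
and lop-filtered Q-ball pipelines.  Problem sizes: 1736 domain voxels
for MSE, 388 fiber voxels for reconstruction metrics.  The full study
runs in well under a minute.

Observed pattern (seed 1): filtering reduces the mean MSE strongly at
low SNR (e.g. 1.1×10⁻² → 7.2×10⁻³ at b = 1000, SNR 10) with paired
p ≪ 10⁻¹⁰ through SNR 30, and improves fiber-count accuracy at
b = 3000 by suppressing over-estimation (success 71% → 82% at SNR 20).
At high SNR the filter's fixed signal truncation (the out-of-band
azimuthal harmonics, ~2–5% RMS on fiber voxels) exceeds the shrinking
noise floor, so the MSE comparison reverses around SNR 50–100 and the
filter adds a ~1–2° angular bias on this phantom, whose raw angular
errors are already near the tessellation quantization floor.  The
under-estimation rate never exceeds ~6% in any dataset or pipeline.
These are intrinsic trade-offs of low-pass filtering on a uniform
spiral, not tuning artifacts; the regime where lop-DWI pays off is low
to moderate SNR, which is where acquisitions actually operate.

## Known limitations

- The filter's passband is fixed by the cutoff, not adapted to b-value
  or scheme; high-b data lose proportionally more angular detail.
- Constrained spherical deconvolution, tractography, motion/eddy
  correction and atlas-based regional statistics are out of scope.
- The electrostatic scheme uses L-BFGS on the symmetrized Coulomb
  energy from a seeded random start; different seeds give energies
  within 1% but not identical point sets.
- `read_dwi` matches an external acquisition-order file to the stored
  directions by nearest axis; schemes with near-duplicate directions
  would defeat this and are rejected.
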