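# Methods

## The model

`nervedti` analyses diffusion-weighted MR volumes of peripheral nerve under
the single diffusion tensor model: the signal of measurement *i* with
b-value *b_i* (s/mm²) and unit gradient direction *ĝ_i* is

    S_i = S0 · exp(−b_i · ĝ_iᵀ D ĝ_i),

with D a symmetric positive (in tissue) 3×3 tensor. Taking logarithms makes
the model linear in the six unique components of D and ln S0, so estimation
is a least-squares solve of a 7-column design with rows
`[−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz, 1]`. The default
estimator is ordinary (unweighted) least squares on the log-signals; a
signal-weighted variant (weights proportional to the signal, the first-order
variance correction for log-transformed Rician data) is available behind
`weighted=True`. The solver works in mm²/s and reports components in
10⁻⁹ m²/s (= 10⁻³ mm²/s); b-values stay in s/mm² throughout.

Diagonalisation gives eigenvalues D1 ≥ D2 ≥ D3 and eigenvectors, from which
the rotation-invariant indices follow: mean diffusivity MD = (D1+D2+D3)/3,
fractional anisotropy FA = √(3/2)·‖D−MD‖/‖D‖ on the eigenvalue triple, and
the axial-to-radial ratio D∥/D⊥ = D1/((D2+D3)/2).

Two estimation modes exist deliberately:

- **voxelwise** fits (maps of eigenvalues/indices), used for tractography
  and display;
- **region-averaged** fits, where the raw signals of all voxels of a
  compartment are averaged per measurement *before* a single tensor fit.
  Because averaging is done on signals, not on fitted quantities, the noise
  floor shrinks with region size and the eigenvalue-repulsion bias that
  inflates voxelwise FA largely disappears. The test suite checks the
  resulting ordering (voxelwise mean FA > region FA at matched noise).

## Numerical choices

- Non-positive signals (possible after noise in heavily attenuated
  measurements) are replaced by a floor — smallest positive signal × 10⁻³ by
  default — and counted on the returned tensor; an all-non-positive vector is
  an error.
- Gradient schemes must contain a b = 0 measurement and at least six
  non-coplanar weighted directions; the design matrix must have rank 7 and a
  b-normalised condition number < 100, otherwise an "insufficient gradient
  scheme" error is raised before any fit.
- Negative eigenvalues from noisy fits pass through the eigensystem
  unchanged (for diagnostics) and are clamped to zero inside the index
  computations, keeping FA in [0, 1]; clamped voxels are flagged and counted
  per run. A fully zero triple has FA defined as 0; D∥/D⊥ with D2+D3 = 0 is
  a "degenerate radial diffusivity" error.
- Eigenvalues are sorted descending with a stable sort; each eigenvector is
  sign-normalised so its largest-magnitude component is positive, making all
  outputs deterministic.
- The shipped 19-direction table (b = 1150 s/mm² plus one b = 0) was
  generated once by seeded electrostatic-repulsion minimisation of the
  antipodal Coulomb energy on the sphere (such acquisitions do not publish
  their tables); its design condition number is ≈ 10.

## The synthetic phantom

The generator emulates an ex vivo median-nerve segment in a signal-free
perfluorinated bath. Defaults are study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| grid | 128 × 64 × 16 | desk-scale grid; 70 µm in-plane (half the 35 µm full-scale resolution), 0.625 mm slices, 9 × 4.5 × 10 mm fov |
| nerve_radius | 1.98 mm | nerve CSA ≈ 12.3 mm² |
| n_fascicles | 6 | within the observed per-slice range |
| fascicle_radius_law | lognormal(ln 0.515, 0.25) mm | size-distribution shape |
| target_fascicular_ratio | 0.46 | fascicle area / nerve area |
| perineurium_thickness | 0.07 mm | one desk-scale voxel (two full-scale voxels); resolvable on purpose — the real sheath is thinner than the resolution |
| fascicle_drift_amplitude | 0.035 mm | sinusoidal in-plane drift of fascicle centres along z, random phase per fascicle; 0 gives a straight extrusion |
| compartment eigenvalues | fascicle (0.81, 0.41, 0.37), perineurium (1.07, 0.75, 0.53), epineurium (0.03, 0.03, 0.03) ·10⁻⁹ m²/s | grand-mean reference values |
| s0 | 100 / 160 / 140 | b = 0 signal: fascicle / perineurium / epineurium (perineurium markedly hyperintense) |
| noise | Rician, σ = s0_fascicle / 14 | calibrated so the b = 0 fascicular SNR ≈ 14 |

Sampled fascicle radii are rescaled so their analytic disk area sums exactly
to the target fascicular ratio: with only a handful of lognormal draws the
ratio would otherwise vary by ±0.1 between seeds, and the fascicular ratio
is a condition of the emulated study, not a random outcome. The radius law
still sets the relative size spread.

Placement packs the fascicle disks — inflated by the perineurium thickness
plus the drift amplitude, so the rings stay disjoint on every slice — inside
the nerve circle by dart-throwing initialisation followed by pairwise
repulsion relaxation. Pure rejection sampling cannot reliably reach the
ring-disk packing fraction (~0.64) that the 0.46 fascicular ratio implies,
whereas the relaxation converges in a few hundred sweeps; a restart budget
bounds the failure probability and exhausting it raises an error naming the
infeasible parameter. Everything is driven by one integer seed (separate
child streams for layout and noise), so label maps and signals are
bit-reproducible.

Fascicle and perineurium tensors point their principal axis along the local
fascicle tangent (drift derivative plus z); each ring voxel inherits the
tangent of its fascicle; the epineurium is isotropic; the bath has zero
tensor and zero signal. Signals follow the Stejskal–Tanner forward model
above; Rician noise is `|S + n1 + i·n2|` with independent N(0, σ²) channels.
SNR estimation divides the mean b = 0 signal of a region by the noise σ
recovered from the Rayleigh-distributed background (SD/√(2 − π/2); the
correction is toggleable).

### What the phantom does and does not emulate

It reproduces the geometry (compartment areas and ratios, slice structure),
the contrast (compartment tensors and b = 0 intensities), the noise level,
and a changing fascicular pattern via centre drift. It does not simulate
k-space/EPI artifacts, T2 decay, partial-volume mixing at compartment
boundaries (labels are crisp), intra-compartment heterogeneity (optional
jitter is off by default), or fascicle splitting/merging. Tests passing on
the phantom therefore validate the *pipeline arithmetic* — fits, indices,
morphometry, statistics, tracking — under realistic geometry and noise; they
do not certify performance on real tissue with segmentation error and
partial volume.

## Morphometry

CSA is voxel count × in-plane voxel area (no sub-voxel polygon estimation,
matching common image-tool practice); the fascicular ratio and the
perineurium/epineurium ratios all use the whole-nerve CSA as denominator, so
maps with unlabelled intra-nerve voxels remain valid. Slice QC is an
explicit include-list in the run configuration rather than an automatic
artifact detector, since such exclusions are visual judgements.

## Statistics

- CoV = sample SD / mean; within-fascicle CoV is taken over slices per
  fascicle, between-fascicle CoV over fascicles per slice; missing cells are
  skipped and counted.
- ICC(1) = (MSB − MSW)/(MSB + (k−1)·MSW) from the one-way random-effects
  ANOVA decomposition, returned unclipped (it can be negative; the floor at
  equal observed subject means is exactly −1/(k−1)); the averaged-ratings
  form ICC(1,k) sits behind a flag. The implementation is cross-checked in
  tests against both a longhand sums-of-squares oracle and
  `pingouin.intraclass_corr`.
- Slice trends and per-nerve regressions use `scipy.stats.linregress`; the
  fascicle-level correlation procedure fits one slope per nerve sample and
  tests the slopes against zero with a one-sample t-test (a zero-variance
  slope set is handled explicitly: p = 1 if the common slope is 0, p below
  machine tolerance otherwise). A pooled Pearson r over all pairs is
  reported alongside, since study reports quote both forms. Its type-I error
  is verified by simulation to sit at α within Monte-Carlo tolerance.
- Compartment contrasts are per-slice percent differences 100·(a−b)/b,
  summarised as mean ± SD.
- No multiple-testing correction is applied; reports carry the number of
  tests run. Normality tests, ANOVA and post-hoc contrasts are out of scope:
  the exported per-group tables feed any general statistics package.

## Tractography and display

Tracking integrates fixed-length Euler steps along the principal
eigenvector, bidirectionally from each seed, re-aligning the (sign-free)
local eigenvector with the previous direction at every step. Defaults —
step = 0.5 × smallest voxel dimension, FA threshold 0.15, turning-angle
limit 60°, seeds at every fascicle voxel of the middle slice — are
conventional deterministic-tractography settings; all are configurable.
Eigenvectors are looked up nearest-neighbour (the phantom's fields are
piecewise constant). Streamlines are exported as TRK; ellipsoid glyphs
(semi-axes proportional to clamped eigenvalues, orientation from the
eigenvectors, RGB = |e1| components) as CSV for any renderer.

## Problem sizes used in validation

The test suite and examples run the phantom at the desk-scale default grid
(128 × 64 × 16, 20 measurements); stochastic checks use 20 phantom seeds for
the region-FA robustness bound and 1000 simulated replicates for the type-I
error of the correlation test. The full-resolution 256 × 128 × 16 geometry
is available by configuration.

## Known limitations

- The log-linear fit is biased at very low SNR (Rician floor); region
  averaging mitigates but does not remove this, and no Rician-likelihood
  estimator is provided.
- Streamline tracking has no interpolation-order options beyond
  nearest/trilinear lookup of e1 and no probabilistic variant.
- The phantom's perineurium is deliberately thicker (resolvable) than real
  perineurium at the simulated resolution; a one-voxel partial-volume stress
  mode is the thinnest it supports.
- Real-data label maps are trusted as given; no segmentation or registration
  is performed.
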