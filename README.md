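# nervedti

Diffusion tensor analysis of peripheral-nerve MR microscopy.

High-field MRI can resolve the internal architecture of a peripheral nerve —
individual fascicles, the thin perineurium sheath around each of them, and the
interfascicular epineurium between them — at tens of micrometres in-plane.
Diffusion tensor imaging (DTI) of such data quantifies how anisotropic water
diffusion is within each compartment and lets one ask whether diffusion
indices relate to fascicular structure. `nervedti` implements that analysis
as a tested, reusable pipeline for researchers working with ex vivo nerve DWI
(or wanting a controlled synthetic testbed for one):

- **Tensor estimation** — log-linear least-squares fit of the single-tensor
  model `S = S0·exp(−b·ĝᵀDĝ)`, per voxel or from region-averaged signals
  (averaging raw signals over a compartment before fitting, which suppresses
  noise far better than averaging voxelwise maps).
- **Scalar indices** — eigenvalues `D1 ≥ D2 ≥ D3` and the standard invariants

  `MD = (D1+D2+D3)/3`,
  `FA = √(3/2)·√(Σ(Dᵢ−MD)²)/√(ΣDᵢ²)`,
  `D∥/D⊥ = D1/((D2+D3)/2)`.
- **Synthetic phantom** — a multi-compartment median-nerve segment (fascicles
  with drifting centres, perineurium rings, epineurium, signal-free bath)
  with ground-truth tensors and Rician noise calibrated to a b = 0 fascicular
  SNR of ≈ 14.
- **Morphometry** — per-slice cross-sectional areas, fascicle counts, and the
  fascicular / perineurium / epineurium area ratios.
- **Statistics** — within/between-fascicle coefficients of variation, one-way
  intraclass correlation ICC(1), slice-wise FA trends, and per-nerve
  regression slopes tested against zero.
- **Tractography & display** — deterministic first-eigenvector streamlines
  (TRK export) and diffusion-ellipsoid glyph tables with the standard
  direction colour map (red |x|, green |y|, blue |z|).

## Worked example

```python
import numpy as np
import nervedti as nd

# a synthetic 9 mm nerve segment: 16 slices, 19 directions at b = 1150 s/mm²
ph = nd.make_phantom(nd.PhantomSpec(seed=0))

snr = nd.estimate_snr(ph.dwi, ph.labels.mask("fascicle"), ph.labels.labels == 0)
print("b0 SNR in fascicles:", round(snr, 2))

# region-averaged tensor of the fascicular compartment
es = nd.eigendecompose(nd.fit_tensor_region(ph.dwi, ph.labels.mask("fascicle")))
idx = nd.compute_indices(es)
print("eigenvalues:", np.round(es.eigenvalues, 3))
print("MD", round(idx.md, 3), "FA", round(idx.fa, 3),
      "D///Dperp", round(idx.axial_radial_ratio, 2))

from nervedti.morphometry import morphometry_table
mt = morphometry_table(ph.labels, ph.spec.voxel_size)
print("fascicular ratio", round(mt.fascicular_ratio.mean(), 3))
```

prints

```
b0 SNR in fascicles: 14.04
eigenvalues: [0.799 0.407 0.368]
MD 0.524 FA 0.426 D///Dperp 2.06
fascicular ratio 0.459
```

The fitted eigenvalues sit within ~1.5 % of the phantom's ground-truth
fascicle triple (0.81, 0.41, 0.37)·10⁻⁹ m²/s despite the SNR-14 Rician
noise, because the fit uses region-averaged signals; the fascicular ratio
matches the generator's 0.46 target up to rasterisation.

The same stages run from the shell via the `nervedti` CLI
(`phantom`, `fit`, `morphometry`, `stats`, `track`, `run`), e.g.

```sh
nervedti run --output-dir out --seed 0
```

writes NIfTI index maps, morphometry and compartment-index TSVs, a stats
JSON, TRK streamlines, an ellipsoid CSV and a reproducibility report.

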