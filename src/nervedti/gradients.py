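"""Diffusion gradient schemes and pulsed-gradient spin-echo acquisition parameters.

A gradient scheme is the list of diffusion weightings applied during the
acquisition: one b-value and one unit direction per measurement, with at
least one unweighted (b = 0) reference image.  Schemes are read and written
in the FSL dialect (a ``.bval`` file with one row of b-values and a
``.bvec`` file with three rows of direction components).

The package ships a fixed 19-direction table at b = 1150 s/mm² plus one
b = 0 image, generated once by electrostatic-repulsion minimisation on the
sphere (antipodal Coulomb energy), matching the acquisition geometry used
for ex vivo median-nerve MR microscopy at 9.4 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "AcquisitionParams",
    "InsufficientGradientSchemeError",
    "GYROMAGNETIC_RATIO",
    "b_value_pgse",
    "optimal_b",
    "default_scheme",
]

#: Proton gyromagnetic ratio in rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.675e8

_UNIT_TOL = 1e-6


class InsufficientGradientSchemeError(ValueError):
    """Raised when a gradient scheme cannot support a tensor fit."""


@dataclass(frozen=True)
class GradientScheme:
    """B-values (s/mm²) and unit gradient directions of an acquisition.

    Parameters
    ----------
    bvals
        Array of shape (n_meas,), non-negative b-values in s/mm².
    bvecs
        Array of shape (n_meas, 3); unit vectors where b > 0 and zero
        vectors where b = 0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
                bvecs = bvecs.T
            else:
                raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs lengths differ")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if not np.all(np.abs(norms[dwi] - 1.0) <= _UNIT_TOL):
            raise ValueError("gradient directions with b > 0 must be unit vectors")
        if np.any(norms[~dwi] > _UNIT_TOL):
            raise ValueError("gradient directions with b = 0 must be zero vectors")
        if not np.any(~dwi):
            raise InsufficientGradientSchemeError(
                "insufficient gradient scheme: no b = 0 measurement"
            )
        if np.count_nonzero(dwi) < 6:
            raise InsufficientGradientSchemeError(
                "insufficient gradient scheme: fewer than 6 diffusion-weighted "
                "measurements"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_meas(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientScheme":
        """Read a scheme from FSL-style bval/bvec text files."""
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)

    def to_fsl(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        """Write the scheme as FSL-style bval/bvec text files."""
        with open(bval_path, "w") as f:
            f.write(" ".join(f"{b:g}" for b in self.bvals) + "\n")
        with open(bvec_path, "w") as f:
            for row in self.bvecs.T:
                f.write(" ".join(f"{x:.10f}" for x in row) + "\n")


def default_scheme() -> GradientScheme:
    """The built-in scheme: one b = 0 image plus 19 directions at b = 1150 s/mm².

    The direction table was generated once by seeded electrostatic-repulsion
    minimisation and is shipped with the package, since acquisitions of this
    kind do not publish their direction tables.
    """
    data = resources.files("nervedti") / "data"
    bvals = np.loadtxt(str(data / "directions19.bval"), ndmin=1).ravel()
    bvecs = np.loadtxt(str(data / "directions19.bvec"), ndmin=2).T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulsed-gradient spin-echo (PGSE) sequence parameters.

    Defaults match a 9.4 T MR-microscopy nerve protocol: TE/TR = 36/880 ms,
    gradient pulse duration δ = 3 ms, separation Δ = 27 ms, amplitude
    G0 = 0.26 T/m, field of view 9 × 4.5 × 10 mm³ over a 256 × 128 × 16
    matrix (35 µm in-plane resolution, 0.625 mm slices).
    """

    delta: float = 3.0        #: gradient pulse duration δ, ms
    Delta: float = 27.0       #: gradient pulse separation Δ, ms
    G0: float = 0.26          #: gradient amplitude, T/m
    TE: float = 36.0          #: echo time, ms
    TR: float = 880.0         #: repetition time, ms
    fov: tuple[float, float, float] = (9.0, 4.5, 10.0)    #: field of view, mm
    matrix: tuple[int, int, int] = (256, 128, 16)         #: sample counts
    gamma: float = GYROMAGNETIC_RATIO                     #: rad s^-1 T^-1

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.Delta):
            raise ValueError("require 0 < delta < Delta")
        for name in ("G0", "TE", "TR", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(f <= 0 for f in self.fov) or any(m <= 0 for m in self.matrix):
            raise ValueError("fov and matrix must be positive")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel size in mm per axis (fov / matrix)."""
        return tuple(f / m for f, m in zip(self.fov, self.matrix))


def b_value_pgse(acq: AcquisitionParams) -> float:
    """Stejskal–Tanner b-value of a PGSE gradient pair, in s/mm².

    b = (γ G0 δ)² (Δ − δ/3) with δ, Δ converted from ms to s.  For the
    default parameters this evaluates to ≈ 1.13 × 10³ s/mm²; the nominal
    sequence value of 1150 additionally includes imaging-gradient
    contributions.
    """
    delta_s = acq.delta * 1e-3
    Delta_s = acq.Delta * 1e-3
    b_si = (acq.gamma * acq.G0 * delta_s) ** 2 * (Delta_s - delta_s / 3.0)  # s/m²
    return b_si * 1e-6


def optimal_b(d: float) -> float:
    """Optimal b-value (s/mm²) of a two-point experiment for diffusivity ``d``.

    For measurements at b1 = 0 and b2 = b, precision of the estimated
    diffusivity is maximised at b = 1.1 / D.  ``d`` is in 10⁻⁹ m²/s
    (= 10⁻³ mm²/s), so the result in s/mm² is 1100 / d.
    """
    if d <= 0:
        raise ValueError("diffusivity must be positive")
    return 1.1 / (d * 1e-3)
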