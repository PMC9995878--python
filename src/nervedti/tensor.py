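"""Log-linear diffusion tensor estimation and rotationally invariant indices.

The single-tensor model relates the diffusion-weighted signal S_i of
measurement i (b-value b_i, unit direction g_i) to the symmetric tensor D:

    S_i = S0 · exp(−b_i · g_iᵀ D g_i)

Taking logarithms makes the model linear in the six unique tensor
components and ln S0, so the fit is an ordinary least-squares solve of a
7-column design (weighted least squares optional).  Tensors can be fitted
per voxel or from region-averaged signals; averaging the raw signals over a
region of interest before fitting suppresses noise far more effectively
than averaging voxelwise index maps.

Diagonalising D yields eigenvalues D1 ≥ D2 ≥ D3 (principal diffusivities,
10⁻⁹ m²/s) and eigenvectors, from which the standard scalar indices follow:

    MD      = (D1 + D2 + D3) / 3
    FA      = √(3/2) · √(Σ(Dᵢ − MD)²) / √(ΣDᵢ²)
    D∥/D⊥   = D1 / ((D2 + D3) / 2)

Units: diffusivities are carried in 10⁻⁹ m²/s (= 10⁻³ mm²/s); b-values in
s/mm².  The 10⁻³ conversion is applied when mapping solver coefficients to
reported components, so the design matrix holds raw b-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gradients import GradientScheme, InsufficientGradientSchemeError

__all__ = [
    "DWIVolume",
    "DiffusionTensor",
    "EigenSystem",
    "DTIndices",
    "build_design_matrix",
    "fit_tensor_lls",
    "fit_tensor_region",
    "fit_dti_volume",
    "eigendecompose",
    "compute_md",
    "compute_fa",
    "compute_axial_radial_ratio",
    "compute_indices",
    "MAX_DESIGN_CONDITION",
]

#: Acceptance bound on the condition number of the (b-normalised) design.
MAX_DESIGN_CONDITION = 100.0


@dataclass
class DWIVolume:
    """4D diffusion-weighted volume with voxel geometry and its scheme.

    ``data`` is indexed (x, y, z, measurement); the fourth axis must match
    ``scheme.n_meas`` and all values must be non-negative.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    scheme: GradientScheme

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, measurement)")
        if self.data.shape[3] != self.scheme.n_meas:
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) != scheme measurements "
                f"({self.scheme.n_meas})"
            )
        if np.any(self.data < 0):
            raise ValueError("DWI signals must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DiffusionTensor:
    """Symmetric diffusion tensor (components in 10⁻⁹ m²/s) with fitted S0."""

    dxx: float
    dyy: float
    dzz: float
    dxy: float
    dxz: float
    dyz: float
    s0: float
    n_floored: int = 0  #: non-positive signals replaced by the floor during the fit

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, s0: float, n_floored: int = 0) -> "DiffusionTensor":
        m = np.asarray(m, dtype=float)
        return cls(
            dxx=m[0, 0], dyy=m[1, 1], dzz=m[2, 2],
            dxy=m[0, 1], dxz=m[0, 2], dyz=m[1, 2],
            s0=float(s0), n_floored=n_floored,
        )


@dataclass
class EigenSystem:
    """Eigenvalues D1 ≥ D2 ≥ D3 (10⁻⁹ m²/s) with orthonormal eigenvectors."""

    d1: float
    d2: float
    d3: float
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3])

    @property
    def eigenvectors(self) -> np.ndarray:
        """Eigenvectors as columns of a 3×3 matrix, ordered e1, e2, e3."""
        return np.column_stack([self.e1, self.e2, self.e3])


@dataclass(frozen=True)
class DTIndices:
    """Scalar tensor indices: MD (10⁻⁹ m²/s), FA in [0, 1], D∥/D⊥ ≥ 0."""

    md: float
    fa: float
    axial_radial_ratio: float
    clamped: bool = False  #: True if negative eigenvalues were clamped to 0


def build_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Design matrix of the log-linear tensor system, shape (n_meas, 7).

    Row i is ``[−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz, 1]``
    so that ``row · [dxx … dyz, ln S0]ᵀ = ln S_i`` with the tensor components
    in mm²/s (reported components are rescaled to 10⁻³ mm²/s = 10⁻⁹ m²/s by
    the fit).

    Raises
    ------
    InsufficientGradientSchemeError
        If the design has rank < 7 or its b-normalised condition number is
        ≥ 100 (directions too close to coplanar for a stable fit).
    """
    b = scheme.bvals[:, None]
    g = scheme.bvecs
    gx, gy, gz = g[:, 0:1], g[:, 1:2], g[:, 2:3]
    design = np.hstack(
        [
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
            np.ones_like(b),
        ]
    )
    if np.linalg.matrix_rank(design) < 7:
        raise InsufficientGradientSchemeError(
            "insufficient gradient scheme: design matrix rank < 7 "
            "(need at least 6 non-coplanar directions and one b = 0)"
        )
    # condition check on a b-normalised copy so the bound is scale-free
    bmax = scheme.bvals.max()
    scaled = design.copy()
    scaled[:, :6] /= bmax
    cond = np.linalg.cond(scaled)
    if cond >= MAX_DESIGN_CONDITION:
        raise InsufficientGradientSchemeError(
            f"insufficient gradient scheme: design condition number {cond:.1f} "
            f">= {MAX_DESIGN_CONDITION:g}"
        )
    return design


def _floor_signals(
    signals: np.ndarray, signal_floor: float | None
) -> tuple[np.ndarray, int]:
    bad = signals <= 0
    n_bad = int(np.count_nonzero(bad))
    if n_bad == 0:
        return signals, 0
    if n_bad == signals.size:
        raise ValueError("all signals are non-positive; cannot fit a tensor")
    if signal_floor is None:
        signal_floor = signals[~bad].min() * 1e-3
    out = signals.copy()
    out[bad] = signal_floor
    warnings.warn(
        f"{n_bad} non-positive signal(s) replaced by floor {signal_floor:g}",
        RuntimeWarning,
        stacklevel=3,
    )
    return out, n_bad


def fit_tensor_lls(
    signals: np.ndarray,
    scheme: GradientScheme,
    *,
    weighted: bool = False,
    signal_floor: float | None = None,
) -> DiffusionTensor:
    """Fit the tensor to one signal vector by log-linear least squares.

    Parameters
    ----------
    signals
        Length ``scheme.n_meas`` vector of non-negative signals.  Values
        ≤ 0 are replaced by ``signal_floor`` (default: smallest positive
        signal × 1e-3) with a warning; the count is recorded on the result.
    weighted
        If True, weight each log-signal by the signal itself (the standard
        first-order variance correction for log-transformed data);
        unweighted ordinary least squares is the default.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.shape[0] != scheme.n_meas:
        raise ValueError("signal vector length does not match the scheme")
    signals, n_floored = _floor_signals(signals, signal_floor)
    design = build_design_matrix(scheme)
    y = np.log(signals)
    if weighted:
        w = signals / signals.max()
        design = design * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    d = coef[:6] * 1e3  # mm²/s -> 10⁻³ mm²/s = 10⁻⁹ m²/s
    return DiffusionTensor(
        dxx=d[0], dyy=d[1], dzz=d[2], dxy=d[3], dxz=d[4], dyz=d[5],
        s0=float(np.exp(coef[6])), n_floored=n_floored,
    )


def fit_tensor_region(
    dwi: DWIVolume,
    mask: np.ndarray,
    *,
    weighted: bool = False,
    signal_floor: float | None = None,
) -> DiffusionTensor:
    """Fit one tensor from region-averaged signals.

    For each measurement the signals of all voxels in ``mask`` (a boolean
    array over the spatial grid) are arithmetically averaged first, and a
    single tensor is fitted to the averaged signal vector.  Averaging the
    raw signals before the fit — rather than averaging voxelwise tensors or
    index maps — is what makes region estimates far less noisy.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask shape does not match the volume")
    if not mask.any():
        raise ValueError("empty region mask")
    mean_signals = dwi.data[mask].mean(axis=0)
    return fit_tensor_lls(
        mean_signals, dwi.scheme, weighted=weighted, signal_floor=signal_floor
    )


def eigendecompose(t: DiffusionTensor) -> EigenSystem:
    """Diagonalise a tensor into sorted eigenvalues and eigenvectors.

    Eigenvalues are sorted descending (stable for ties); each eigenvector
    is sign-normalised so that its largest-magnitude component is positive,
    making the output deterministic.  Negative eigenvalues pass through
    unchanged — clamping happens in the index computations.
    """
    m = t.as_matrix()
    if not np.all(np.isfinite(m)):
        raise ValueError("tensor components must be finite")
    vals, vecs = np.linalg.eigh(m)  # ascending
    order = np.arange(2, -1, -1)
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(3):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return EigenSystem(
        d1=float(vals[0]), d2=float(vals[1]), d3=float(vals[2]),
        e1=vecs[:, 0].copy(), e2=vecs[:, 1].copy(), e3=vecs[:, 2].copy(),
    )


def _clamped(es: EigenSystem, clamp_negative: bool) -> np.ndarray:
    vals = es.eigenvalues
    if clamp_negative:
        vals = np.clip(vals, 0.0, None)
    return vals


def compute_md(es: EigenSystem) -> float:
    """Mean diffusivity (D1 + D2 + D3) / 3, in 10⁻⁹ m²/s."""
    return float(es.eigenvalues.mean())


def compute_fa(es: EigenSystem, *, clamp_negative: bool = True) -> float:
    """Fractional anisotropy √(3/2)·‖D − MD‖ / ‖D‖, in [0, 1].

    Negative eigenvalues (possible in noisy voxelwise fits) are clamped to
    zero by default, which keeps the value inside [0, 1].  An all-zero
    triple has no anisotropy direction and returns 0 by convention.
    """
    vals = _clamped(es, clamp_negative)
    norm2 = float(np.sum(vals**2))
    if norm2 == 0.0:
        return 0.0
    md = vals.mean()
    fa = np.sqrt(1.5 * np.sum((vals - md) ** 2) / norm2)
    return float(min(fa, 1.0)) if clamp_negative else float(fa)


def compute_axial_radial_ratio(es: EigenSystem, *, clamp_negative: bool = True) -> float:
    """Axial-to-radial diffusivity ratio D1 / ((D2 + D3) / 2)."""
    vals = _clamped(es, clamp_negative)
    radial = (vals[1] + vals[2]) / 2.0
    if radial == 0.0:
        raise ValueError("degenerate radial diffusivity: D2 + D3 = 0")
    return float(vals[0] / radial)


def compute_indices(es: EigenSystem, *, clamp_negative: bool = True) -> DTIndices:
    """All three scalar indices from one eigensystem, clamping consistently."""
    vals = _clamped(es, clamp_negative)
    clamped = bool(np.any(es.eigenvalues < 0)) and clamp_negative
    md = float(vals.mean())
    fa = compute_fa(es, clamp_negative=clamp_negative)
    radial = (vals[1] + vals[2]) / 2.0
    ratio = float(vals[0] / radial) if radial > 0 else float("nan")
    return DTIndices(md=md, fa=fa, axial_radial_ratio=ratio, clamped=clamped)


def fit_dti_volume(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    *,
    weighted: bool = False,
    clamp_negative: bool = True,
) -> dict[str, np.ndarray]:
    """Voxelwise tensor fit over a volume, vectorised.

    Returns a dict of maps over the spatial grid: ``evals`` (…, 3, sorted
    descending, raw), ``evecs`` (…, 3, 3; columns are eigenvectors), ``md``,
    ``fa``, ``axial_radial_ratio``, ``s0``, and ``clamped`` (bool map of
    voxels whose indices involved clamping).  Voxels outside ``mask`` hold
    NaN (0 for s0).  The per-voxel math is identical to
    :func:`fit_tensor_lls` followed by :func:`eigendecompose`.
    """
    if mask is None:
        mask = np.ones(dwi.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sig = dwi.data[mask]  # (nvox, nmeas)
    if sig.size == 0:
        raise ValueError("empty fit mask")
    floor = np.where(sig > 0, sig, np.inf).min() * 1e-3
    sig = np.where(sig > 0, sig, floor)
    design = build_design_matrix(dwi.scheme)
    y = np.log(sig)
    if weighted:
        w = sig / sig.max(axis=1, keepdims=True)  # (nvox, nmeas)
        # per-voxel weighted solve: loop-free via normal equations
        aw = design[None, :, :] * w[:, :, None]
        yw = y * w
        coef = np.stack(
            [np.linalg.lstsq(aw[i], yw[i], rcond=None)[0] for i in range(sig.shape[0])]
        )
    else:
        coef = (np.linalg.pinv(design) @ y.T).T  # (nvox, 7)
    d = coef[:, :6] * 1e3
    s0 = np.exp(coef[:, 6])
    tensors = np.empty((d.shape[0], 3, 3))
    tensors[:, 0, 0] = d[:, 0]
    tensors[:, 1, 1] = d[:, 1]
    tensors[:, 2, 2] = d[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d[:, 5]
    vals, vecs = np.linalg.eigh(tensors)  # ascending
    vals = vals[:, ::-1]
    vecs = vecs[:, :, ::-1]
    # deterministic sign: largest-magnitude component positive
    k = np.argmax(np.abs(vecs), axis=1)  # (nvox, 3)
    signs = np.sign(np.take_along_axis(vecs, k[:, None, :], axis=1))[:, 0, :]
    signs[signs == 0] = 1.0
    vecs = vecs * signs[:, None, :]

    cl = np.clip(vals, 0.0, None) if clamp_negative else vals
    md = cl.mean(axis=1)
    norm2 = np.sum(cl**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum((cl - md[:, None]) ** 2, axis=1) / norm2)
        radial = (cl[:, 1] + cl[:, 2]) / 2.0
        ratio = cl[:, 0] / radial
    fa = np.where(norm2 == 0, 0.0, fa)
    if clamp_negative:
        fa = np.minimum(fa, 1.0)

    shape = dwi.shape
    out: dict[str, np.ndarray] = {}

    def scatter(values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        arr = np.full(shape + values.shape[1:], fill)
        arr[mask] = values
        return arr

    out["evals"] = scatter(vals)
    out["evecs"] = scatter(vecs)
    out["md"] = scatter(md)
    out["fa"] = scatter(fa)
    out["axial_radial_ratio"] = scatter(ratio)
    out["s0"] = scatter(s0, fill=0.0)
    clamped_map = np.zeros(shape, dtype=bool)
    clamped_map[mask] = np.any(vals < 0, axis=1)
    out["clamped"] = clamped_map
    return out
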