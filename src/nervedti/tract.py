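"""Deterministic first-eigenvector streamline tractography and ellipsoid glyphs.

Streamlines are integrated with fixed-step Euler steps along the principal
eigenvector field, bidirectionally from each seed, with the usual
deterministic-tractography stopping rules: low fractional anisotropy,
sharp turning angle, volume exit, or a step budget.  Eigenvector fields
are line fields (sign-free), so each step re-aligns the local eigenvector
with the previous direction; flipping all signs leaves the geometry
unchanged.

Diffusion ellipsoid glyphs encode the local tensor: semi-axes proportional
to the eigenvalues, orientation from the eigenvectors, and the standard
direction colour map on the principal axis (red |x|, green |y|, blue |z|).
Glyphs are exported as CSV for any renderer; streamlines as TRK.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Streamline",
    "EllipsoidGlyph",
    "TrackingParams",
    "track_streamlines",
    "eigenvector_rgb",
    "ellipsoid_field",
    "seeds_from_mask",
    "save_trk",
    "glyphs_to_dataframe",
]


@dataclass
class Streamline:
    """Ordered 3D points (mm) with the step length and termination reason."""

    points: np.ndarray
    step_mm: float
    termination: str  # low_fa | high_angle | out_of_volume | max_steps


@dataclass(frozen=True)
class EllipsoidGlyph:
    """One diffusion ellipsoid: centre (mm), semi-axes, rotation, colour."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: np.ndarray  # 3x3, columns e1, e2, e3
    rgb: tuple[float, float, float]


@dataclass(frozen=True)
class TrackingParams:
    """Deterministic tractography parameters (conventional defaults)."""

    step_mm: float | None = None  #: None -> 0.5 × smallest voxel dimension
    fa_min: float = 0.15
    angle_max_deg: float = 60.0
    max_steps: int = 2000

    def resolve_step(self, voxel_size: tuple[float, float, float]) -> float:
        return self.step_mm if self.step_mm is not None else 0.5 * min(voxel_size)


def eigenvector_rgb(e1: np.ndarray) -> np.ndarray:
    """Direction colour of a principal eigenvector: (|x|, |y|, |z|)."""
    return np.abs(np.asarray(e1, dtype=float))


def _voxel_of(p: np.ndarray, voxel_size: np.ndarray, shape: tuple[int, ...]) -> tuple | None:
    idx = np.floor(p / voxel_size).astype(int)
    if np.any(idx < 0) or np.any(idx >= shape):
        return None
    return tuple(idx)


def _trace(
    seed: np.ndarray,
    init_dir: np.ndarray,
    e1: np.ndarray,
    fa: np.ndarray,
    voxel_size: np.ndarray,
    params: TrackingParams,
    step: float,
) -> tuple[list[np.ndarray], str]:
    shape = fa.shape
    cos_max = math.cos(math.radians(params.angle_max_deg))
    points = [seed.copy()]
    direction = init_dir
    p = seed.copy()
    for _ in range(params.max_steps):
        p = p + direction * step
        vox = _voxel_of(p, voxel_size, shape)
        if vox is None:
            points.append(p)
            return points, "out_of_volume"
        if not (fa[vox] >= params.fa_min):  # False also for NaN
            return points, "low_fa"
        d = e1[vox].astype(float)
        nrm = np.linalg.norm(d)
        if nrm == 0 or not np.all(np.isfinite(d)):
            return points, "low_fa"
        d = d / nrm
        if float(np.dot(d, direction)) < 0:
            d = -d
        if float(np.dot(d, direction)) < cos_max:
            return points, "high_angle"
        points.append(p)
        direction = d
    return points, "max_steps"


def track_streamlines(
    e1: np.ndarray,
    fa: np.ndarray,
    seeds: np.ndarray,
    voxel_size: tuple[float, float, float],
    params: TrackingParams | None = None,
) -> list[Streamline]:
    """Bidirectional Euler tracking along the principal eigenvector field.

    Parameters
    ----------
    e1
        Principal-eigenvector field, shape (X, Y, Z, 3); treated as a line
        field (sign-free).  Nearest-neighbour lookup.
    fa
        Fractional anisotropy map, shape (X, Y, Z); NaN stops a track.
    seeds
        (N, 3) seed positions in mm.  Seeds below ``fa_min`` are skipped;
        if none survive, an empty list is returned with a warning.
    """
    params = params or TrackingParams()
    voxel_size = np.asarray(voxel_size, dtype=float)
    step = params.resolve_step(tuple(voxel_size))
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    out: list[Streamline] = []
    for seed in seeds:
        vox = _voxel_of(seed, voxel_size, fa.shape)
        if vox is None or not (fa[vox] >= params.fa_min):
            continue
        d0 = e1[vox].astype(float)
        nrm = np.linalg.norm(d0)
        if nrm == 0:
            continue
        d0 = d0 / nrm
        fwd, term_f = _trace(seed, d0, e1, fa, voxel_size, params, step)
        bwd, term_b = _trace(seed, -d0, e1, fa, voxel_size, params, step)
        pts = np.vstack([np.array(bwd[::-1]), np.array(fwd[1:])])
        if pts.shape[0] < 2:
            continue
        # report the forward termination; the backward one ends the head
        out.append(Streamline(points=pts, step_mm=step, termination=term_f))
    if not out:
        warnings.warn("no seeds above the FA threshold", RuntimeWarning, stacklevel=2)
    return out


def seeds_from_mask(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    slice_index: int | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Voxel-centre seed positions (mm) from a boolean mask.

    With ``slice_index`` only that z-slice is seeded (the conventional
    "every fascicle voxel on the middle slice" seeding); ``stride``
    subsamples the voxel list deterministically.
    """
    mask = np.asarray(mask, dtype=bool)
    if slice_index is not None:
        keep = np.zeros_like(mask)
        keep[:, :, slice_index] = mask[:, :, slice_index]
        mask = keep
    idx = np.argwhere(mask)[::stride]
    return (idx + 0.5) * np.asarray(voxel_size, dtype=float)


def ellipsoid_field(
    evals: np.ndarray,
    evecs: np.ndarray,
    voxel_size: tuple[float, float, float],
    mask: np.ndarray | None = None,
    subsample: int = 1,
    scale: float = 1.0,
) -> list[EllipsoidGlyph]:
    """One glyph per retained voxel with eigenvalue-proportional semi-axes.

    ``evals`` is (X, Y, Z, 3) descending, ``evecs`` (X, Y, Z, 3, 3) with
    eigenvectors in columns.  ``subsample`` keeps every n-th voxel per
    axis; zero tensors are skipped; negative eigenvalues are clamped to 0
    for the axes (near-isotropic compartments appear as small dots).
    """
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    vs = np.asarray(voxel_size, dtype=float)
    if mask is None:
        mask = np.all(np.isfinite(evals), axis=-1)
    glyphs: list[EllipsoidGlyph] = []
    sub = (slice(None, None, subsample),) * 3
    idx = np.argwhere(mask[sub]) * subsample
    for i, j, k in idx:
        v = evals[i, j, k]
        if not np.all(np.isfinite(v)) or np.all(v <= 0):
            continue
        axes = np.clip(v, 0.0, None) * scale
        e1 = evecs[i, j, k][:, 0]
        glyphs.append(
            EllipsoidGlyph(
                center=tuple((np.array([i, j, k]) + 0.5) * vs),
                semi_axes=tuple(axes),
                orientation=evecs[i, j, k],
                rgb=tuple(eigenvector_rgb(e1 / np.linalg.norm(e1))),
            )
        )
    return glyphs


def glyphs_to_dataframe(glyphs: list[EllipsoidGlyph]) -> pd.DataFrame:
    """Flatten glyphs to a table (centre, axes, rotation matrix, rgb)."""
    rows = []
    for g in glyphs:
        row = dict(
            cx=g.center[0], cy=g.center[1], cz=g.center[2],
            ax1=g.semi_axes[0], ax2=g.semi_axes[1], ax3=g.semi_axes[2],
            r=g.rgb[0], g=g.rgb[1], b=g.rgb[2],
        )
        for a in range(3):
            for b in range(3):
                row[f"rot{a}{b}"] = float(g.orientation[a, b])
        rows.append(row)
    return pd.DataFrame(rows)


def save_trk(
    streamlines: list[Streamline],
    voxel_size: tuple[float, float, float],
    shape: tuple[int, int, int],
    path: str | Path,
) -> None:
    """Write streamlines (point coordinates in mm) to a TRK file."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    affine = np.diag([*voxel_size, 1.0])
    tractogram = Tractogram(
        [s.points for s in streamlines], affine_to_rasmm=np.eye(4)
    )
    header = {
        "voxel_sizes": tuple(float(v) for v in voxel_size),
        "dimensions": tuple(int(s) for s in shape),
        "voxel_to_rasmm": affine,
        "voxel_order": "RAS",
    }
    TrkFile(tractogram, header).save(str(path))
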