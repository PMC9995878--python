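"""Per-slice fascicular morphometry and compartment signal extraction.

Morphometry follows voxel-counting conventions: the cross-sectional area
(CSA) of a structure on a transverse slice is its voxel count times the
in-plane voxel area, and the fascicular ratio (FR) is the summed fascicle
CSA divided by the whole-nerve CSA.  Ratios always use the nerve CSA as
denominator (never the compartment sum), so maps with unlabelled
intra-nerve voxels — common in manual segmentations — remain valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import CompartmentLabelMap
from .tensor import (
    DWIVolume,
    compute_indices,
    eigendecompose,
    fit_tensor_lls,
)

__all__ = [
    "MorphometryRecord",
    "compute_csa",
    "compute_ratios",
    "extract_region_signals",
    "morphometry_table",
    "compartment_index_table",
]


@dataclass(frozen=True)
class MorphometryRecord:
    """Morphometry of one slice: CSAs in mm², ratios dimensionless."""

    nerve_id: str
    slice_index: int
    n_fascicles: int
    fascicle_csa: tuple[float, ...]
    nerve_csa: float
    fascicular_ratio: float
    perineurium_ratio: float
    epineurium_ratio: float


def compute_csa(mask: np.ndarray, voxel_size: tuple[float, ...]) -> float:
    """Cross-sectional area of a 2D slice mask: voxel count × in-plane area."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("CSA is defined on a 2D slice mask")
    n = int(np.count_nonzero(mask))
    if n == 0:
        warnings.warn("empty mask: CSA = 0", RuntimeWarning, stacklevel=2)
    return n * float(voxel_size[0]) * float(voxel_size[1])


def compute_ratios(
    labels: CompartmentLabelMap,
    slice_index: int,
    voxel_size: tuple[float, ...],
    nerve_id: str = "phantom",
) -> MorphometryRecord:
    """Fascicular, perineurium and epineurium ratios of one slice."""
    sl = labels.labels[:, :, slice_index]
    nerve_csa = compute_csa(sl > 0, voxel_size)
    if nerve_csa == 0:
        raise ValueError(f"nerve CSA is zero on slice {slice_index}")
    fasc_csa = []
    for lab in labels.fascicle_labels:
        m = sl == lab
        if m.any():
            fasc_csa.append(compute_csa(m, voxel_size))
    peri_csa = compute_csa(sl == labels.perineurium_label, voxel_size)
    epi_csa = compute_csa(sl == labels.epineurium_label, voxel_size)
    return MorphometryRecord(
        nerve_id=nerve_id,
        slice_index=slice_index,
        n_fascicles=len(fasc_csa),
        fascicle_csa=tuple(fasc_csa),
        nerve_csa=nerve_csa,
        fascicular_ratio=sum(fasc_csa) / nerve_csa,
        perineurium_ratio=peri_csa / nerve_csa,
        epineurium_ratio=epi_csa / nerve_csa,
    )


def extract_region_signals(
    dwi: DWIVolume,
    labels: CompartmentLabelMap,
    compartment: str | int,
    slices: slice | list[int] | None = None,
) -> np.ndarray:
    """Per-measurement mean signal over one compartment (optionally sliced).

    ``compartment`` is a legend name ('fascicle', 'perineurium',
    'epineurium', 'nerve') or an integer label.  Raises ``KeyError`` listing
    the available compartments if absent.
    """
    if isinstance(compartment, str):
        mask3d = labels.mask(compartment)
    else:
        if compartment not in labels.legend:
            raise KeyError(
                f"label {compartment} not in legend; available labels: "
                f"{sorted(labels.legend)}"
            )
        mask3d = labels.label_mask(int(compartment))
    if slices is not None:
        keep = np.zeros(mask3d.shape[2], dtype=bool)
        keep[slices] = True
        mask3d = mask3d & keep[None, None, :]
    if not mask3d.any():
        raise KeyError(
            f"compartment {compartment!r} has no voxels in the selected slices"
        )
    return dwi.data[mask3d].mean(axis=0)


def morphometry_table(
    labels: CompartmentLabelMap,
    voxel_size: tuple[float, ...],
    nerve_id: str = "phantom",
    slices: list[int] | None = None,
) -> pd.DataFrame:
    """One morphometry row per included slice."""
    nz = labels.labels.shape[2]
    rows = []
    for z in slices if slices is not None else range(nz):
        r = compute_ratios(labels, z, voxel_size, nerve_id=nerve_id)
        rows.append(
            dict(
                nerve_id=r.nerve_id,
                slice=r.slice_index,
                n_fascicles=r.n_fascicles,
                nerve_csa=r.nerve_csa,
                mean_fascicle_csa=float(np.mean(r.fascicle_csa)) if r.fascicle_csa else 0.0,
                fascicular_ratio=r.fascicular_ratio,
                perineurium_ratio=r.perineurium_ratio,
                epineurium_ratio=r.epineurium_ratio,
            )
        )
    return pd.DataFrame(rows)


def compartment_index_table(
    dwi: DWIVolume,
    labels: CompartmentLabelMap,
    nerve_id: str = "phantom",
    slices: list[int] | None = None,
    *,
    weighted: bool = False,
) -> pd.DataFrame:
    """Region-fit tensor indices per slice and compartment.

    For each included slice, a tensor is fitted from the region-averaged
    signals of every individual fascicle, of the pooled compartments
    (fascicle/perineurium/epineurium) and of the whole nerve, and the
    eigenvalues plus MD / FA / D∥⁄D⊥ are tabulated.  Columns: nerve_id,
    slice, compartment, label, d1, d2, d3, md, fa, axial_radial_ratio,
    n_voxels.
    """
    nz = labels.labels.shape[2]
    rows = []
    targets: list[tuple[str, str | int]] = [(f"fascicle_{lab}", lab) for lab in labels.fascicle_labels]
    targets += [
        ("fascicle", "fascicle"),
        ("perineurium", "perineurium"),
        ("epineurium", "epineurium"),
        ("nerve", "nerve"),
    ]
    for z in slices if slices is not None else range(nz):
        for name, key in targets:
            try:
                sig = extract_region_signals(dwi, labels, key, slices=[z])
            except KeyError:
                continue
            if isinstance(key, int):
                n_vox = int(np.count_nonzero(labels.labels[:, :, z] == key))
            elif key == "nerve":
                n_vox = int(np.count_nonzero(labels.labels[:, :, z] > 0))
            else:
                n_vox = int(
                    np.count_nonzero(labels.mask(key)[:, :, z])
                )
            es = eigendecompose(fit_tensor_lls(sig, dwi.scheme, weighted=weighted))
            idx = compute_indices(es)
            rows.append(
                dict(
                    nerve_id=nerve_id, slice=z, compartment=name,
                    label=key if isinstance(key, int) else -1,
                    d1=es.d1, d2=es.d2, d3=es.d3,
                    md=idx.md, fa=idx.fa,
                    axial_radial_ratio=idx.axial_radial_ratio,
                    n_voxels=n_vox,
                )
            )
    return pd.DataFrame(rows)
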