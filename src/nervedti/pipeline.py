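"""End-to-end pipeline: phantom or real data → fit → morphometry → stats → tracts.

A run is described by a :class:`RunConfig` (YAML-loadable).  In phantom
mode the synthetic generator produces the inputs; otherwise a 4D NIfTI
volume, FSL bval/bvec files and an integer label map (with a JSON legend)
are read from disk.  Every run writes TSV/JSON/NIfTI/TRK outputs into the
output directory plus a report carrying the configuration hash, the seed,
package versions and warning counts, so reruns with the same
configuration reproduce every numeric table exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gradients import GradientScheme
from .morphometry import compartment_index_table, morphometry_table
from .phantom import (
    CompartmentLabelMap,
    PhantomSpec,
    estimate_snr,
    export_phantom,
    make_phantom,
)
from .stats import SliceSeries, compartment_contrast, cov_within_between, slice_trend
from .tensor import DWIVolume, fit_dti_volume
from .tract import TrackingParams, save_trk, seeds_from_mask, track_streamlines, \
    ellipsoid_field, glyphs_to_dataframe

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI flags override file values)."""

    output_dir: str = "nervedti_out"
    nerve_id: str = "phantom"
    seed: int = 0
    # input mode: phantom (default) or paths to real data
    use_phantom: bool = True
    phantom: dict = field(default_factory=dict)  #: PhantomSpec overrides
    dwi_path: str | None = None
    bval_path: str | None = None
    bvec_path: str | None = None
    labels_path: str | None = None
    legend_path: str | None = None
    # fit options
    weighted_fit: bool = False
    clamp_negative: bool = True
    # QC: slices included in morphometry/statistics (None = all)
    included_slices: list[int] | None = None
    # tracking
    tracking: dict = field(default_factory=dict)  #: TrackingParams overrides
    seed_stride: int = 1
    ellipsoid_subsample: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.use_phantom:
        spec_kwargs = dict(config.phantom)
        spec_kwargs.setdefault("seed", config.seed)
        for key in ("grid", "voxel_size"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = PhantomSpec(**spec_kwargs)
        data = make_phantom(spec)
        return data.dwi, data.labels, data
    import nibabel as nib

    for name in ("dwi_path", "bval_path", "bvec_path", "labels_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{name} missing or not found: {p}")
    scheme = GradientScheme.from_fsl(config.bval_path, config.bvec_path)
    img = nib.load(config.dwi_path)
    dwi = DWIVolume(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        scheme=scheme,
    )
    lab_img = nib.load(config.labels_path)
    lab = np.asarray(lab_img.dataobj).astype(int)
    if config.legend_path:
        raw = json.loads(Path(config.legend_path).read_text())
        legend = {int(k): str(v) for k, v in raw.items()}
    else:  # conventional layout: 1..K fascicles, K+1 perineurium, K+2 epineurium
        present = sorted(int(v) for v in np.unique(lab) if v > 0)
        legend = {v: "fascicle" for v in present[:-2]}
        if len(present) >= 2:
            legend[present[-2]] = "perineurium"
            legend[present[-1]] = "epineurium"
    labels = CompartmentLabelMap(labels=lab, legend=legend)
    return dwi, labels, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns the report dict (also written to ``report.json``).  Stage
    failures raise :class:`PipelineError` naming the stage; outputs of
    completed stages are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "nervedti_version": __version__,
        "config": config.to_dict(),
        "warnings": 0,
        "stages": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage = "inputs"
        try:
            dwi, labels, phantom_data = _load_inputs(config)
            if phantom_data is not None:
                export_phantom(phantom_data, outdir / "phantom")
                bg = labels.labels == 0
                report["snr_estimate_fascicle_b0"] = estimate_snr(
                    dwi, labels.mask("fascicle"), bg
                )
            report["stages"].append(stage)

            stage = "fit"
            maps = fit_dti_volume(
                dwi, labels.mask("nerve"),
                weighted=config.weighted_fit, clamp_negative=config.clamp_negative,
            )
            _save_maps(maps, dwi.voxel_size, outdir)
            report["clamped_voxels"] = int(np.count_nonzero(maps["clamped"]))
            report["stages"].append(stage)

            stage = "morphometry"
            morpho = morphometry_table(
                labels, dwi.voxel_size, nerve_id=config.nerve_id,
                slices=config.included_slices,
            )
            morpho.to_csv(outdir / "morphometry.tsv", sep="\t", index=False)
            comp = compartment_index_table(
                dwi, labels, nerve_id=config.nerve_id,
                slices=config.included_slices, weighted=config.weighted_fit,
            )
            comp.to_csv(outdir / "compartment_indices.tsv", sep="\t", index=False)
            report["stages"].append(stage)

            stage = "stats"
            report["stats"] = _run_stats(comp, morpho)
            report["stages"].append(stage)

            stage = "track"
            seeds = seeds_from_mask(
                labels.mask("fascicle"), dwi.voxel_size,
                slice_index=labels.labels.shape[2] // 2,
                stride=config.seed_stride,
            )
            params = TrackingParams(**config.tracking)
            lines = track_streamlines(
                maps["evecs"][..., :, 0], maps["fa"], seeds, dwi.voxel_size, params
            )
            save_trk(lines, dwi.voxel_size, dwi.shape, outdir / "tracts.trk")
            glyphs = ellipsoid_field(
                maps["evals"], maps["evecs"], dwi.voxel_size,
                mask=labels.mask("nerve"), subsample=config.ellipsoid_subsample,
            )
            glyphs_to_dataframe(glyphs).to_csv(outdir / "ellipsoids.csv", index=False)
            report["n_streamlines"] = len(lines)
            report["n_glyphs"] = len(glyphs)
            report["stages"].append(stage)
        except Exception as exc:  # annotate with the failing stage
            report["failed_stage"] = stage
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise PipelineError(stage, exc) from exc

        report["warnings"] = len(caught)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _save_maps(maps: dict, voxel_size, outdir: Path) -> None:
    import nibabel as nib

    affine = np.diag([*voxel_size, 1.0])
    for name in ("md", "fa", "axial_radial_ratio", "s0", "evals"):
        nib.save(nib.Nifti1Image(maps[name], affine), outdir / f"{name}.nii.gz")
    nib.save(
        nib.Nifti1Image(maps["evecs"].reshape(*maps["fa"].shape, 9), affine),
        outdir / "evecs.nii.gz",
    )


def _run_stats(comp: pd.DataFrame, morpho: pd.DataFrame) -> dict:
    """Within-run statistics from the compartment and morphometry tables."""
    out: dict = {"n_tests": 0}
    nerve = comp[comp.compartment == "nerve"].sort_values("slice")
    if len(nerve) >= 3:
        slope, r, p = slice_trend(
            SliceSeries(nerve["slice"].to_numpy(), nerve["fa"].to_numpy())
        )
        out["nerve_fa_slice_trend"] = {"slope": slope, "r": r, "p": p}
        out["n_tests"] += 1
    fasc = comp[comp.compartment.str.startswith("fascicle_")]
    if not fasc.empty:
        pivot = fasc.pivot_table(index="label", columns="slice", values="fa")
        if pivot.shape[0] >= 2 and pivot.shape[1] >= 2:
            within, between, skipped = cov_within_between(pivot)
            out["fa_cov"] = {
                "within_fascicle_mean": float(np.nanmean(within)),
                "between_fascicle_mean": float(np.nanmean(between)),
                "cells_skipped": skipped,
            }
    paired = comp.pivot_table(index="slice", columns="compartment", values="md")
    if {"perineurium", "fascicle"} <= set(paired.columns):
        mean_pct, sd_pct = compartment_contrast(
            paired["perineurium"].to_numpy(), paired["fascicle"].to_numpy()
        )
        out["perineurium_vs_fascicle_md_pct"] = {"mean": mean_pct, "sd": sd_pct}
    if {"epineurium", "fascicle"} <= set(paired.columns):
        mean_pct, sd_pct = compartment_contrast(
            paired["epineurium"].to_numpy(), paired["fascicle"].to_numpy()
        )
        out["epineurium_vs_fascicle_md_pct"] = {"mean": mean_pct, "sd": sd_pct}
    out["morphometry_means"] = {
        "fascicular_ratio": float(morpho["fascicular_ratio"].mean()),
        "perineurium_ratio": float(morpho["perineurium_ratio"].mean()),
        "epineurium_ratio": float(morpho["epineurium_ratio"].mean()),
        "n_fascicles": float(morpho["n_fascicles"].mean()),
        "nerve_csa_mm2": float(morpho["nerve_csa"].mean()),
    }
    return out
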