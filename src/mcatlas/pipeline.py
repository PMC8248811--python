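"""End-to-end atlas pipeline orchestration and on-disk layout.

``run_pipeline`` chains the two registration/averaging stages, the
temporal Gompertz fit and (optionally) the growth-rate parcellation,
writing a reproducible output tree:

::

    out/
      config.yaml                 # full configuration echo
      warps/<subject>.nii.gz      # stage-2 warps to reference space
      templates/<channel>/t<center>.nii.gz
      unbias/warp_t<center>.nii.gz, affine_t<center>.yaml
      params/<channel>/{alpha,delta,gamma,tau,r_squared,...}.nii.gz
      params/warp/..., params/affine.yaml
      atlas.yaml                  # channel kinds, lmax, fitted t range
      checksums.json              # sha256 of every written array

Re-running with identical inputs and configuration reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .atlas import TemplateSeries, build_atlas_stage
from .images import ChannelSet, ScalarImage, SHImage
from .io import PipelineConfig, write_displacement, write_image
from .parcellation import average_growth_rate_map, threshold_parcellation
from .temporal import GompertzParams, fit_atlas4d

logger = logging.getLogger(__name__)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=np.float64).tobytes()).hexdigest()


def _series_reference(templates: dict[str, TemplateSeries], reference: ChannelSet) -> ChannelSet:
    """Assemble the stage-1 global template set as the stage-2 reference."""
    from .images import Channel

    chans = []
    for ch in reference:
        series = templates[ch.name]
        chans.append(Channel(ch.name, series.templates[0], ch.role))
    return ChannelSet("template-1", reference.age, chans)


def _write_params(params: GompertzParams, affine: np.ndarray, directory: Path, checksums: dict):
    import nibabel as nib

    directory.mkdir(parents=True, exist_ok=True)
    for field in ("alpha", "delta", "gamma", "tau", "r_squared", "linear_slope", "linear_r_squared"):
        arr = getattr(params, field)
        if arr.ndim == 3:
            write_image(ScalarImage(arr, affine), directory / f"{field}.nii.gz")
        else:  # per-coefficient / per-component parameter stack
            nib.save(
                nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine),
                str(directory / f"{field}.nii.gz"),
            )
        checksums[str(directory.name) + "/" + field] = _checksum(arr)


def run_pipeline(
    cohort: list[ChannelSet],
    reference: ChannelSet,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run stages 1-2, the temporal fit and optional parcellation.

    Returns a dict with the in-memory results (``records``,
    ``templates``, ``unbias``, ``atlas``, ``checksums``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    checksums: dict[str, str] = {}
    logger.info("pipeline start: %d subjects, seed %d", len(cohort), config.seed)

    records1, templates1, _ = build_atlas_stage(cohort, reference, 1, config.atlas)
    y1 = _series_reference(templates1, reference)
    records, templates, unbias = build_atlas_stage(cohort, y1, 2, config.atlas)

    warp_dir = out / "warps"
    warp_dir.mkdir(exist_ok=True)
    for rec in records:
        sid = rec.channelset.subject_id
        write_displacement(rec.warp_to_reference, warp_dir / f"{sid}.nii.gz")
        checksums[f"warps/{sid}"] = _checksum(rec.warp_to_reference.vectors)

    for name, series in templates.items():
        ch_dir = out / "templates" / name
        ch_dir.mkdir(parents=True, exist_ok=True)
        for center, template in zip(series.centers, series.templates):
            write_image(template, ch_dir / f"t{center:.1f}.nii.gz")
            arr = template.coeffs if isinstance(template, SHImage) else template.values
            checksums[f"templates/{name}/t{center:.1f}"] = _checksum(arr)

    unb_dir = out / "unbias"
    unb_dir.mkdir(exist_ok=True)
    for center, warp, aff in zip(unbias.centers, unbias.warps, unbias.affines):
        write_displacement(warp, unb_dir / f"warp_t{center:.1f}.nii.gz")
        (unb_dir / f"affine_t{center:.1f}.yaml").write_text(
            yaml.safe_dump({"matrix": aff.matrix.tolist(), "flags": sorted(aff.flags)})
        )
        checksums[f"unbias/warp_t{center:.1f}"] = _checksum(warp.vectors)
        checksums[f"unbias/affine_t{center:.1f}"] = _checksum(aff.matrix)

    roles = {ch.name: ch.role for ch in reference}
    atlas = fit_atlas4d(templates, unbias, roles)
    for name, params in atlas.channel_params.items():
        _write_params(params, atlas.voxel_to_world, out / "params" / name, checksums)
    if atlas.warp_params is not None:
        _write_params(atlas.warp_params, atlas.voxel_to_world, out / "params" / "warp", checksums)
    if atlas.affine_params is not None:
        aff_d = {
            f: getattr(atlas.affine_params, f).tolist()
            for f in ("alpha", "delta", "gamma", "tau", "r_squared")
        }
        (out / "params" / "affine.yaml").write_text(yaml.safe_dump(aff_d))
    (out / "atlas.yaml").write_text(
        yaml.safe_dump(
            {
                "channels": {n: list(k) for n, k in atlas.channel_kinds.items()},
                "t_range": list(atlas.t_range),
                "grid_shape": list(atlas.grid_shape),
            }
        )
    )

    parcellation = None
    gamma_names = [c for c in config.parcellation.gamma_channels if c in atlas.channel_params]
    if gamma_names:
        gamma_maps = {
            n: ScalarImage(atlas.channel_params[n].gamma, atlas.voxel_to_world)
            for n in gamma_names
            if atlas.channel_params[n].gamma.ndim == 3
        }
        if gamma_maps:
            gamma_av = average_growth_rate_map(gamma_maps)
            parcellation = threshold_parcellation(
                gamma_av, config.parcellation.threshold, config.parcellation.min_region_voxels
            )
            write_image(ScalarImage(gamma_av.values, gamma_av.voxel_to_world), out / "gamma_av.nii.gz")
            write_image(
                ScalarImage(parcellation.labels.astype(float), parcellation.voxel_to_world),
                out / "parcellation.nii.gz",
            )
            checksums["gamma_av"] = _checksum(gamma_av.values)
            checksums["parcellation"] = _checksum(parcellation.labels)

    (out / "checksums.json").write_text(json.dumps(checksums, indent=1, sort_keys=True))
    logger.info("pipeline done: %d checksums", len(checksums))
    return {
        "records": records,
        "templates": templates,
        "unbias": unbias,
        "atlas": atlas,
        "parcellation": parcellation,
        "checksums": checksums,
    }
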