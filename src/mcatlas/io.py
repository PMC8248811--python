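"""NIfTI readers/writers, cohort manifests and pipeline configuration.

File conventions
----------------
* scalar and mask channels: 3D NIfTI (masks carry ``mcatlas:mask`` in
  the header description);
* SH/ODF channels: 4D NIfTI whose 4th dimension indexes the real
  even-order SH coefficients in the package (l, m) lexicographic order
  (see :mod:`mcatlas.sh`); the volume count must equal
  ``(L+1)(L+2)/2`` for an even L;
* displacement fields: 4D NIfTI with 3 volumes of world-mm vector
  components, tagged ``mcatlas:dispfield``;
* manifests and result tables: UTF-8 tab-separated text.  A manifest has
  columns ``subject_id``, ``age``, optional ``ga_at_birth`` and
  ``group``, and one ``channel:<name>:<role>`` column per channel
  holding file paths.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasConfig
from .errors import FormatError
from .images import (
    AnyImage,
    Channel,
    ChannelSet,
    DisplacementField,
    MaskImage,
    ScalarImage,
    SHImage,
    n_coeffs,
)
from .registration import RegistrationConfig

_MASK_TAG = "mcatlas:mask"
_FIELD_TAG = "mcatlas:dispfield"


def _lmax_for_count(count: int) -> int | None:
    lmax = 0
    while n_coeffs(lmax) < count:
        lmax += 2
    return lmax if n_coeffs(lmax) == count else None


def write_image(image: AnyImage, path: str | Path) -> None:
    """Write a Scalar/Mask/SH image as NIfTI."""
    if isinstance(image, SHImage):
        data = image.coeffs
        descrip = f"mcatlas:sh lmax={image.lmax}"
    else:
        data = image.values
        descrip = _MASK_TAG if isinstance(image, MaskImage) else "mcatlas:scalar"
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), image.voxel_to_world)
    img.header["descrip"] = descrip.encode()
    nib.save(img, str(path))


def read_channel(path: str | Path, expected_role: str | None = None) -> AnyImage:
    """Load a channel, inferring its type from dimensionality and the
    header description; 4D volumes must have a valid even-order SH count."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: non-invertible voxel-to-world affine")
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    if data.ndim == 4:
        if _FIELD_TAG in descrip or (expected_role == "dispfield"):
            raise FormatError(f"{path}: displacement field; use read_displacement")
        lmax = _lmax_for_count(data.shape[3])
        if lmax is None:
            raise FormatError(
                f"{path}: {data.shape[3]} volumes match no even-order SH coefficient count"
            )
        return SHImage(data, lmax, affine)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D or 4D volume, got ndim={data.ndim}")
    is_mask = expected_role == "mask" or _MASK_TAG in descrip
    if is_mask:
        return MaskImage((data >= 0.5).astype(float), affine)
    return ScalarImage(data, affine)


def write_displacement(field: DisplacementField, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float64), field.voxel_to_world)
    img.header["descrip"] = _FIELD_TAG.encode()
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_displacement(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(f"{path}: a displacement field needs 3 component volumes")
    return DisplacementField(data, np.asarray(img.affine, dtype=float))


# ---------------------------------------------------------------------------
# manifests

def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns or "age" not in df.columns:
        raise FormatError(f"{path}: manifest needs subject_id and age columns")
    base = Path(path).parent
    for col in df.columns:
        if col.startswith("channel:"):
            for i, p in df[col].items():
                full = Path(p) if Path(p).is_absolute() else base / p
                if not full.exists():
                    raise FormatError(f"{path} row {i}: missing file {p}")
                df.loc[i, col] = str(full)
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any():
        raise FormatError(f"{path}: ages must be positive numbers")
    return df


def load_cohort(manifest: pd.DataFrame) -> list[ChannelSet]:
    """Read every subject's channels from a manifest DataFrame."""
    cohort = []
    chan_cols = [c for c in manifest.columns if c.startswith("channel:")]
    for _, row in manifest.iterrows():
        channels = []
        for col in chan_cols:
            _, name, role = col.split(":", 2)
            channels.append(Channel(name, read_channel(row[col], role), role))
        cohort.append(ChannelSet(str(row["subject_id"]), float(row["age"]), channels))
    return cohort


def save_channelset(cs: ChannelSet, directory: str | Path) -> dict[str, str]:
    """Write each channel as ``<name>.nii.gz``; returns name -> filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for ch in cs:
        fname = f"{ch.name}.nii.gz"
        write_image(ch.image, directory / fname)
        out[ch.name] = fname
    return out


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class ParcellationConfig:
    threshold: float = 0.25
    min_region_voxels: int = 27
    sd_threshold: float = 1.5
    gamma_channels: tuple[str, ...] = ("t1w", "t2w")


@dataclasses.dataclass
class PipelineConfig:
    """Umbrella configuration; round-trips losslessly through YAML."""

    atlas: AtlasConfig = dataclasses.field(default_factory=AtlasConfig)
    parcellation: ParcellationConfig = dataclasses.field(default_factory=ParcellationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        atlas_d = dict(d.get("atlas", {}))
        reg_d = dict(atlas_d.pop("registration", {}))
        for key in ("level_scales", "lmax_schedule", "max_iterations_per_level"):
            if key in reg_d and reg_d[key] is not None:
                reg_d[key] = tuple(reg_d[key])
        for key in ("window_centers", "stage1_channels", "stage2_channels"):
            if key in atlas_d and atlas_d[key] is not None:
                atlas_d[key] = tuple(atlas_d[key])
        parc_d = dict(d.get("parcellation", {}))
        if "gamma_channels" in parc_d and parc_d["gamma_channels"] is not None:
            parc_d["gamma_channels"] = tuple(parc_d["gamma_channels"])
        return cls(
            atlas=AtlasConfig(registration=RegistrationConfig(**reg_d), **atlas_d),
            parcellation=ParcellationConfig(**parc_d),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
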