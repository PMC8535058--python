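"""Domain types and file I/O for multi-echo T2-mapping studies.

Conventions
-----------
Arrays are indexed ``(echo, z, y, x)`` for signal volumes and ``(z, y, x)``
for masks and maps, where ``z`` is the through-plane (slice) axis. Voxel
spacing is given as ``(dz, dy, dx)`` in mm; physical coordinates are
voxel-center positions ``index * spacing`` (mm), 0-based.

Volumes are stored as NIfTI (echoes stacked on the 4th axis) with a JSON
sidecar carrying echo times (ms), specimen id, loading configuration and,
for masks, the label map. All downstream stages consume the in-memory
types defined here; nothing re-reads files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Configuration",
    "MultiEchoVolume",
    "LabelMask",
    "T2Map",
    "StudyManifest",
    "ManifestRecord",
    "DEFAULT_LABEL_MAP",
    "read_multiecho",
    "write_multiecho",
    "read_mask",
    "write_mask",
]


class Configuration(str, Enum):
    """Loading configuration of the joint during acquisition."""

    UNLOADED_D0 = "d0"
    LOADED_D1 = "d1"


#: Default integer labels for the segmented structures.
DEFAULT_LABEL_MAP: dict[int, str] = {
    1: "PCL",
    2: "ACL",
    3: "FEMUR",
    4: "TIBIA",
    5: "MENISCUS_AM",
    6: "MENISCUS_PM",
    7: "MENISCUS_AL",
    8: "MENISCUS_PL",
}


class InputError(ValueError):
    """Raised when an input file or argument violates a contract."""


@dataclass
class MultiEchoVolume:
    """A 4D multi-echo spin-echo acquisition.

    Parameters
    ----------
    signal : ndarray, shape (n_echoes, nz, ny, nx)
        Magnitude signal, arbitrary units, nonnegative.
    echo_times : ndarray
        Echo times in ms, strictly increasing, one per echo.
    voxel_spacing : tuple of float
        ``(dz, dy, dx)`` in mm, all positive.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    voxel_spacing: tuple[float, float, float]
    specimen_id: str = ""
    configuration: Configuration = Configuration.UNLOADED_D0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.echo_times = np.asarray(self.echo_times, dtype=np.float64)
        self.configuration = Configuration(self.configuration)
        if self.signal.ndim != 4:
            raise InputError(f"signal must be 4D (echo,z,y,x), got {self.signal.ndim}D")
        if self.echo_times.ndim != 1 or len(self.echo_times) != self.signal.shape[0]:
            raise InputError(
                f"{len(self.echo_times)} echo times for {self.signal.shape[0]} echoes"
            )
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise InputError("echo times must be positive and strictly increasing")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise InputError(f"voxel spacing must be 3 positive reals, got {self.voxel_spacing}")
        if np.any(self.signal < 0):
            raise InputError("magnitude signal must be nonnegative")

    @property
    def n_echoes(self) -> int:
        return self.signal.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]


@dataclass
class LabelMask:
    """Integer segmentation labels aligned to a :class:`MultiEchoVolume` grid.

    0 is background; positive integers name structures via ``label_map``.
    """

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    voxel_spacing: tuple[float, float, float] = (3.2, 0.4, 0.4)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = np.rint(labels).astype(np.int32)
            if not np.allclose(labels, as_int):
                raise InputError("mask voxel values must be integers")
            labels = as_int
        if labels.ndim != 3:
            raise InputError(f"mask must be 3D, got {labels.ndim}D")
        if labels.min() < 0:
            raise InputError("labels must be nonnegative")
        self.labels = labels
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        unknown = set(np.unique(labels)) - {0} - set(self.label_map)
        if unknown:
            warnings.warn(f"mask contains unmapped labels {sorted(unknown)}; retained")

    def mask_for(self, structure: str) -> np.ndarray:
        """Boolean mask of a named structure (all-False if absent)."""
        for lab, name in self.label_map.items():
            if name == structure:
                return self.labels == lab
        return np.zeros_like(self.labels, dtype=bool)

    def structures_present(self) -> list[str]:
        present = set(np.unique(self.labels)) - {0}
        return [name for lab, name in sorted(self.label_map.items()) if lab in present]


@dataclass
class T2Map:
    """Per-voxel mono-exponential fit results.

    Invalid voxels carry NaN in ``t2``/``s0``/``r2_adj``; ``valid`` marks
    voxels that converged, passed the adjusted-R² gate, and lie inside the
    configured T2 bounds.
    """

    t2: np.ndarray
    s0: np.ndarray
    r2_adj: np.ndarray
    valid: np.ndarray
    voxel_spacing: tuple[float, float, float]
    r2_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (self.t2.shape == self.s0.shape == self.r2_adj.shape == self.valid.shape):
            raise InputError("t2/s0/r2_adj/valid shapes must agree")
        self.valid = self.valid.astype(bool)


@dataclass(frozen=True)
class ManifestRecord:
    specimen_id: str
    configuration: Configuration
    volume_path: Path
    mask_path: Path


@dataclass
class StudyManifest:
    """Pairing of each specimen's unloaded (d0) and loaded (d1) acquisitions."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        self.records = [
            ManifestRecord(r.specimen_id, Configuration(r.configuration),
                           Path(r.volume_path), Path(r.mask_path))
            for r in self.records
        ]

    @property
    def specimen_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.specimen_id not in seen:
                seen.append(r.specimen_id)
        return seen

    def validate_paired(self) -> None:
        """Every specimen must appear in exactly both configurations."""
        bad = []
        for sid in self.specimen_ids:
            configs = sorted(r.configuration.value for r in self.records if r.specimen_id == sid)
            if configs != ["d0", "d1"]:
                bad.append((sid, configs))
        if bad:
            raise InputError(f"unpaired specimens: {bad}")

    def to_csv(self, path: Path | str) -> None:
        pd.DataFrame(
            [
                {
                    "specimen_id": r.specimen_id,
                    "configuration": r.configuration.value,
                    "volume_path": str(r.volume_path),
                    "mask_path": str(r.mask_path),
                }
                for r in self.records
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "StudyManifest":
        df = pd.read_csv(path)
        return cls(
            [
                ManifestRecord(str(row.specimen_id), Configuration(row.configuration),
                               Path(row.volume_path), Path(row.mask_path))
                for row in df.itertuples()
            ]
        )


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_multiecho(volume: MultiEchoVolume, path: Path | str) -> Path:
    """Write a volume as NIfTI (x,y,z,echo on disk) plus JSON sidecar."""
    path = Path(path)
    data = np.transpose(volume.signal, (3, 2, 1, 0))  # -> x,y,z,echo
    nib.save(nib.Nifti1Image(data, _affine(volume.voxel_spacing)), str(path))
    sidecar = {
        "echo_times_ms": volume.echo_times.tolist(),
        "specimen_id": volume.specimen_id,
        "configuration": volume.configuration.value,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_multiecho(path: Path | str, echo_times: Sequence[float] | None = None) -> MultiEchoVolume:
    """Read a 4D multi-echo NIfTI volume.

    Echo times come from the JSON sidecar unless passed explicitly; the
    count must match the 4th dimension. Spacing is read from the header.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise InputError(f"{path}: expected 4D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise InputError(f"{path}: missing or invalid voxel spacing in header")
    sidecar = _sidecar_path(path)
    meta: dict = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if echo_times is None:
        if "echo_times_ms" not in meta:
            raise InputError(f"{path}: echo times not supplied and no sidecar found")
        echo_times = meta["echo_times_ms"]
    echo_times = np.asarray(echo_times, dtype=np.float64)
    if len(echo_times) != data.shape[3]:
        raise InputError(
            f"{path}: {len(echo_times)} echo times for {data.shape[3]} echoes"
        )
    order = np.argsort(echo_times)
    signal = np.transpose(data, (3, 2, 1, 0))[order]  # -> echo,z,y,x, TE ascending
    # NIfTI stores zooms as float32; round away the representation error
    dx, dy, dz = (float(np.format_float_positional(z, precision=6, fractional=False))
                  for z in zooms)
    return MultiEchoVolume(
        signal=signal,
        echo_times=echo_times[order],
        voxel_spacing=(dz, dy, dx),
        specimen_id=str(meta.get("specimen_id", "")),
        configuration=Configuration(meta.get("configuration", "d0")),
    )


def write_mask(mask: LabelMask, path: Path | str) -> Path:
    path = Path(path)
    data = np.transpose(mask.labels.astype(np.int16), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(mask.voxel_spacing)), str(path))
    _sidecar_path(path).write_text(
        json.dumps({"label_map": {str(k): v for k, v in mask.label_map.items()}}, indent=1)
    )
    return path


def read_mask(
    path: Path | str,
    volume: MultiEchoVolume,
    label_map: Mapping[int, str] | None = None,
) -> LabelMask:
    """Read a label mask and check alignment with its volume."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected 3D mask, got {data.ndim}D")
    labels = np.transpose(data, (2, 1, 0))
    if labels.shape != volume.spatial_shape:
        raise InputError(
            f"{path}: mask shape {labels.shape} != volume shape {volume.spatial_shape}"
        )
    if label_map is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            raw = json.loads(sidecar.read_text()).get("label_map", {})
            label_map = {int(k): v for k, v in raw.items()}
        else:
            label_map = dict(DEFAULT_LABEL_MAP)
    return LabelMask(labels=labels, label_map=dict(label_map), voxel_spacing=volume.voxel_spacing)
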