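"""Volume readers/writers, report serialization and run configuration.

Volumes are exchanged as NIfTI (preferred), DICOM series (read-only) or raw
binary with a YAML sidecar header.  Masks go out as NIfTI, surfaces as
PLY/OBJ meshes, polar maps as CSV (and PNG bullseyes), reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pydicom
import yaml

from .geometry import ScalarVolume

DIALECTS = ("nifti", "dicom", "raw")


class VolumeReadError(RuntimeError):
    """Unreadable or ambiguous volume input; the message names the dialect."""


def read_volume(
    path: str | Path,
    dialect: Optional[str] = None,
    spacing_override: Optional[tuple[float, float, float]] = None,
) -> ScalarVolume:
    """Read a volume from NIfTI, a DICOM series directory, or raw+YAML.

    Spacing comes from the header; reading fails loudly when the header
    carries no usable spacing unless ``spacing_override`` is given.
    """
    path = Path(path)
    if dialect is None:
        if path.is_dir():
            dialect = "dicom"
        elif path.suffix in (".yaml", ".yml"):
            dialect = "raw"
        else:
            dialect = "nifti"
    if dialect not in DIALECTS:
        raise VolumeReadError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "nifti":
        vol = _read_nifti(path)
    elif dialect == "dicom":
        vol = _read_dicom_series(path)
    else:
        vol = _read_raw(path)
    if spacing_override is not None:
        vol = ScalarVolume(data=vol.data, spacing=spacing_override)
    return vol


def _read_nifti(path: Path) -> ScalarVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeReadError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeReadError(
            f"NIfTI {path} has no positive voxel spacing; pass a spacing override"
        )
    return ScalarVolume(data=np.clip(data, 0, None), spacing=tuple(float(z) for z in zooms))


def _read_dicom_series(path: Path) -> ScalarVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise VolumeReadError(f"no DICOM files found in {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if len(slices) < 2:
        raise VolumeReadError(f"DICOM series in {path} has fewer than 2 image slices")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    except Exception as exc:
        raise VolumeReadError("DICOM slices lack ImagePositionPatient") from exc
    dz = np.diff(zs)
    if np.ptp(dz) > 1e-3 * max(abs(dz.mean()), 1e-9) + 1e-6:
        raise VolumeReadError("inconsistent DICOM slice spacing")
    try:
        py, px = (float(v) for v in slices[0].PixelSpacing)
    except Exception as exc:
        raise VolumeReadError("DICOM header lacks PixelSpacing") from exc
    stack = np.stack([ds.pixel_array.astype(float) for ds in slices], axis=-1)
    # pixel_array is (row=y, col=x); reorder to (x, y, z)
    data = np.transpose(stack, (1, 0, 2))
    return ScalarVolume(data=np.clip(data, 0, None), spacing=(px, py, float(abs(dz.mean()))))


def _read_raw(header_path: Path) -> ScalarVolume:
    with open(header_path) as fh:
        hdr = yaml.safe_load(fh)
    for key in ("file", "shape", "dtype", "spacing_mm"):
        if key not in hdr:
            raise VolumeReadError(f"raw header {header_path} is missing {key!r}")
    raw_path = header_path.parent / hdr["file"]
    shape = tuple(int(n) for n in hdr["shape"])
    data = np.fromfile(raw_path, dtype=np.dtype(hdr["dtype"]))
    if data.size != int(np.prod(shape)):
        raise VolumeReadError(
            f"raw file {raw_path} holds {data.size} values, header declares {np.prod(shape)}"
        )
    return ScalarVolume(
        data=np.clip(data.reshape(shape).astype(float), 0, None),
        spacing=tuple(float(s) for s in hdr["spacing_mm"]),
    )


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a volume (or float data) as NIfTI with the spacing in the affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Export a triangle mesh as PLY or OBJ (by file extension)."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(str(path))


def write_polar_map_csv(pmap, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        pmap.grid,
        index=[f"polar_{i}" for i in range(pmap.n_polar)],
        columns=[f"az_{j}" for j in range(pmap.n_azimuth)],
    )
    df.to_csv(path)


def write_polar_map_png(pmap, path: str | Path) -> None:
    """Bullseye rendering of the polar map (apex at the center)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    az = np.linspace(0, 2 * np.pi, pmap.n_azimuth + 1)
    rad = np.linspace(0, 1, pmap.n_polar + 1)
    A, R = np.meshgrid(az, rad)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    pc = ax.pcolormesh(A, R, np.nan_to_num(pmap.grid[::-1]), cmap="inferno", vmin=0)
    ax.set_yticklabels([])
    fig.colorbar(pc, ax=ax, label="RV count / LV max")
    fig.savefig(path, dpi=120)
    plt.close(fig)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder, allow_nan=True)


@dataclass
class RunConfig:
    """Command-line / YAML configuration of one run.

    Houses the semiautomatic user interactions (LV bounding box, RV sphere
    adjustment) as non-interactive overrides so runs stay scriptable.
    """

    input_path: Optional[str] = None
    dialect: Optional[str] = None
    spacing_override: Optional[tuple[float, float, float]] = None
    lv_box: Optional[tuple[int, int, int, int, int, int]] = None  # lo+hi voxel
    rv_center: Optional[tuple[float, float, float]] = None  # mm
    rv_radius: Optional[float] = None  # mm
    wall_mm: float = 12.8
    n_polar: int = 18
    n_azimuth: int = 36
    ratio_threshold: float = 30.0
    prior_angle_deg: float = 0.0
    output_dir: str = "."
    seed: Optional[int] = None  # simulation only
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.spacing_override is not None and any(
            s <= 0 for s in self.spacing_override
        ):
            raise ValueError("spacing override must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spacing_override", "lv_box", "rv_center"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)
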