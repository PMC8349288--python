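"""On-disk formats: NIfTI-1 / PNG rasters, complex k-space with JSON sidecar,
CSV trajectories and histories, JSON configs and reports.

Images and phase maps travel as single-slice NIfTI-1 (float64, lossless) or
as PNG (8/16-bit, a scaled convenience export).  Complex k-space has no
standard single-file container, so it is stored either as a two-channel
(real, imaginary) float32 NIfTI with the channels on the third axis, or as a
little-endian complex64 raw file — both accompanied by a JSON sidecar
``<file>.json`` recording the grid size, centering and convention.  Reading
k-space without its sidecar is an error, not a guess.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import FormatError, SidecarError
from .kspace import Image, KSpaceData, MotionTrajectory
from .roi import ROIMask

__all__ = [
    "write_image", "read_image", "write_kspace", "read_kspace",
    "write_mask", "read_mask", "write_trajectory", "read_trajectory",
    "write_history", "read_history", "write_json", "read_json",
]

KSPACE_CONVENTION = "cycles-per-FOV, unitary"
_NIFTI_EXTS = (".nii", ".nii.gz")
_IDENTITY_AFFINE = np.eye(4)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_image(img: Image | np.ndarray, path: str | Path) -> Path:
    """Write a real 2-D image as NIfTI (lossless float64) or 16-bit PNG.

    PNG output linearly rescales [0, max] to the uint16 range; use NIfTI when
    exact values matter.
    """
    path = Path(path)
    arr = np.asarray(img.pixels if isinstance(img, Image) else img)
    if np.iscomplexobj(arr):
        arr = np.abs(arr)
    arr = arr.astype(np.float64)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr, _IDENTITY_AFFINE), str(path))
    elif path.suffix.lower() == ".png":
        peak = arr.max()
        scaled = np.zeros_like(arr) if peak == 0 else arr / peak
        iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
    else:
        raise FormatError(f"unknown image extension: {path.name}")
    return path


def read_image(path: str | Path) -> Image:
    """Read an image written by :func:`write_image` (PNG returns values in [0, 1])."""
    path = Path(path)
    if _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        arr = np.squeeze(arr)
    elif path.suffix.lower() == ".png":
        raw = iio.imread(path)
        arr = np.asarray(raw, dtype=np.float64)
        if raw.dtype == np.uint16:
            arr /= 65535.0
        elif raw.dtype == np.uint8:
            arr /= 255.0
    else:
        raise FormatError(f"unknown image extension: {path.name}")
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a single 2-D slice, got {arr.shape}")
    return Image(arr)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_kspace(ks: KSpaceData, path: str | Path) -> Path:
    """Write complex k-space (2-channel float32 NIfTI or raw complex64) + sidecar."""
    path = Path(path)
    if _is_nifti(path):
        stacked = np.stack(
            [ks.samples.real, ks.samples.imag], axis=2).astype(np.float32)
        nib.save(nib.Nifti1Image(stacked, _IDENTITY_AFFINE), str(path))
    elif path.suffix.lower() == ".cplx":
        ks.samples.astype("<c8").tofile(path)
    else:
        raise FormatError(f"unknown k-space extension: {path.name}")
    sidecar = {
        "size": ks.size,
        "centered": True,
        "convention": KSPACE_CONVENTION,
        "dtype": "complex64",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_kspace(path: str | Path) -> KSpaceData:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise SidecarError(f"missing k-space sidecar: {sidecar_file.name}")
    meta = json.loads(sidecar_file.read_text())
    size = int(meta["size"])
    if _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise FormatError(
                f"{path.name}: expected a (N, N, 2) real/imaginary stack, "
                f"got {arr.shape}"
            )
        samples = arr[:, :, 0] + 1j * arr[:, :, 1]
    elif path.suffix.lower() == ".cplx":
        flat = np.fromfile(path, dtype="<c8")
        if flat.size != size * size:
            raise FormatError(
                f"{path.name}: expected {size * size} complex64 samples, "
                f"got {flat.size}"
            )
        samples = flat.reshape(size, size).astype(np.complex128)
    else:
        raise FormatError(f"unknown k-space extension: {path.name}")
    if samples.shape != (size, size):
        raise FormatError(
            f"{path.name}: data shape {samples.shape} disagrees with sidecar size {size}"
        )
    return KSpaceData(samples, centered=bool(meta.get("centered", True)))


def write_mask(roi: ROIMask, path: str | Path) -> Path:
    """Write a binary mask as 8-bit PNG {0, 255} or uint8 NIfTI."""
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), _IDENTITY_AFFINE),
                 str(path))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.where(roi.mask, 255, 0).astype(np.uint8))
    else:
        raise FormatError(f"unknown mask extension: {path.name}")
    return path


def read_mask(path: str | Path, method_tag: str = "oracle") -> ROIMask:
    path = Path(path)
    if _is_nifti(path):
        arr = np.squeeze(np.asarray(nib.load(str(path)).dataobj))
    elif path.suffix.lower() == ".png":
        arr = iio.imread(path)
    else:
        raise FormatError(f"unknown mask extension: {path.name}")
    return ROIMask(np.asarray(arr) > 0, method_tag=method_tag)


def write_trajectory(traj: MotionTrajectory, path: str | Path) -> Path:
    """CSV with header ``ky,p,q`` (0-based row index)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ky", "p", "q"])
        for ky in range(traj.size):
            writer.writerow([ky, repr(float(traj.p[ky])), repr(float(traj.q[ky]))])
    return path


def read_trajectory(path: str | Path) -> MotionTrajectory:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["ky", "p", "q"]:
            raise FormatError(
                f"{path.name}: expected trajectory CSV header 'ky,p,q', got {header}"
            )
        rows = [(int(ky), float(p), float(q)) for ky, p, q in reader]
    rows.sort(key=lambda r: r[0])
    if [r[0] for r in rows] != list(range(len(rows))):
        raise FormatError(f"{path.name}: ky column must enumerate 0..N-1")
    p = np.array([r[1] for r in rows])
    q = np.array([r[2] for r in rows])
    return MotionTrajectory(p, q, model="custom")


def write_history(history, path: str | Path) -> Path:
    """Per-iteration convergence series, columns ``iteration,support_violation_energy``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "support_violation_energy"])
        for i, value in enumerate(history):
            writer.writerow([i, repr(float(value))])
    return path


def read_history(path: str | Path) -> list[float]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0] != "iteration":
            raise FormatError(f"{path.name}: expected history CSV header")
        return [float(row[1]) for row in reader]


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
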