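"""Volume I/O and preprocessing for per-orbit axial stacks.

Conventions
-----------
Arrays are stored ``(z, y, x)`` = (slice, row, column).  Physical
coordinates are measured at voxel centers: ``x = column * sx``,
``y = row * sy``, ``z = slice_index * sz`` (all in mm).  NIfTI files are
written with a diagonal affine ``diag(sx, sy, sz, 1)`` and the on-disk
``(i, j, k)`` axes mapped to ``(x, y, z)``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

Side = Literal["left", "right", "unsplit"]

BACKGROUND, EYEBALL, OPTIC_NERVE = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", EYEBALL: "eyeball", OPTIC_NERVE: "optic_nerve"}


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel spacing in mm.

    ``sx``/``sy`` are the in-plane spacings (column/row), ``sz`` the slice
    thickness used by the volume and distance formulas.
    """

    sx: float
    sy: float
    sz: float
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0 and self.sz > 0):
            raise ValueError(f"spacings must be positive, got {(self.sx, self.sy, self.sz)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.sx * self.sy * self.sz

    @property
    def in_plane_max(self) -> float:
        return max(self.sx, self.sy)


@dataclass
class LabeledVolume:
    """An intensity stack with an optional 3-class label stack.

    Labels: 0 = background, 1 = eyeball, 2 = optic nerve.
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    labels: Optional[np.ndarray] = None
    side: Side = "unsplit"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.intensities.shape:
                raise ValueError(
                    f"label shape {self.labels.shape} != intensity shape {self.intensities.shape}"
                )
            bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, EYEBALL, OPTIC_NERVE])
            if bad.size:
                raise ValueError(f"labels contain values outside {{0,1,2}}: {bad}")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SliceSample:
    """One axial slice plus its position in the stack (for the 2.5D model)."""

    image: np.ndarray
    slice_index: int
    n_slices: int
    geometry: VoxelGeometry
    mask: Optional[np.ndarray] = None
    side: Side = "unsplit"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.slice_index < self.n_slices):
            raise ValueError(
                f"slice_index {self.slice_index} outside [0, {self.n_slices})"
            )


def _affine(geom: VoxelGeometry) -> np.ndarray:
    return np.diag([geom.sx, geom.sy, geom.sz, 1.0])


def write_volume(volume: LabeledVolume, path: os.PathLike | str,
                 labels_path: os.PathLike | str | None = None) -> None:
    """Write intensities (and labels, if present) as NIfTI."""
    import nibabel as nib

    aff = _affine(volume.geometry)
    # (z, y, x) -> on-disk (x, y, z)
    img = nib.Nifti1Image(np.ascontiguousarray(volume.intensities.T).astype(np.float32), aff)
    nib.save(img, str(path))
    if volume.labels is not None and labels_path is not None:
        lab = nib.Nifti1Image(np.ascontiguousarray(volume.labels.T).astype(np.uint8), aff)
        nib.save(lab, str(labels_path))


def read_volume(path: os.PathLike | str,
                labels_path: os.PathLike | str | None = None,
                format: str | None = None,
                side: Side = "unsplit",
                subject_id: str = "") -> LabeledVolume:
    """Read a volume from NIfTI or a DICOM series directory.

    ``format`` is inferred from the path when omitted: directories are read
    as DICOM series, ``.nii``/``.nii.gz`` files as NIfTI.  Spacing metadata
    must be present; otherwise the file is rejected.
    """
    p = Path(path)
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        intensities, geom = _read_nifti(p)
    elif format == "dicom_series":
        intensities, geom = _read_dicom_series(p)
    else:
        raise ValueError(f"unsupported format {format!r} (expected 'nifti' or 'dicom_series')")

    labels = None
    if labels_path is not None:
        lab_arr, lab_geom = _read_nifti(Path(labels_path))
        if lab_arr.shape != intensities.shape:
            raise ValueError("label volume shape does not match intensity volume")
        labels = np.rint(lab_arr).astype(np.uint8)
    return LabeledVolume(intensities=intensities, geometry=geom, labels=labels,
                         side=side, subject_id=subject_id)


def _read_nifti(path: Path) -> tuple[np.ndarray, VoxelGeometry]:
    import nibabel as nib

    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)  # (x, y, z)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return np.ascontiguousarray(data.T).astype(np.float32), VoxelGeometry(*map(float, zooms))


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, VoxelGeometry]:
    import pydicom

    files = sorted(q for q in directory.iterdir() if q.suffix.lower() in {".dcm", ".ima", ""})
    if not files:
        raise ValueError(f"{directory}: no DICOM files found")
    slices = [pydicom.dcmread(str(f)) for f in files]

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    ds0 = slices[0]
    if not hasattr(ds0, "PixelSpacing"):
        raise ValueError(f"{directory}: DICOM series lacks PixelSpacing metadata")
    sy, sx = (float(v) for v in ds0.PixelSpacing)  # row spacing, column spacing
    if len(slices) > 1:
        sz = abs(z_of(slices[1]) - z_of(ds0))
    else:
        sz = float(getattr(ds0, "SliceThickness", 0.0))
    if sz <= 0:
        raise ValueError(f"{directory}: cannot determine slice spacing")
    stack = np.stack([s.pixel_array.astype(np.float32) for s in slices], axis=0)
    return stack, VoxelGeometry(sx=sx, sy=sy, sz=sz)


def split_orbits(volume: LabeledVolume) -> tuple[LabeledVolume, LabeledVolume]:
    """Split an unsplit head volume into left/right orbit halves.

    The cut is at the mid-sagittal column ``nx // 2``.  By radiological
    convention the patient's right orbit occupies the lower column indices,
    so columns ``[0, mid)`` become the *right* volume and ``[mid, nx)`` the
    *left*.  Every voxel of the input lands in exactly one half.
    """
    if volume.side != "unsplit":
        raise ValueError(f"volume already split (side={volume.side!r})")
    nx = volume.shape[2]
    mid = nx // 2

    def half(sl: slice, side: Side) -> LabeledVolume:
        return LabeledVolume(
            intensities=volume.intensities[:, :, sl].copy(),
            labels=None if volume.labels is None else volume.labels[:, :, sl].copy(),
            geometry=volume.geometry, side=side, subject_id=volume.subject_id,
        )

    return half(slice(0, mid), "right"), half(slice(mid, nx), "left")


def crop_to_roi(volume: LabeledVolume, margin_voxels: int = 0) -> LabeledVolume:
    """Crop to the bounding box of the labeled structures plus a margin.

    The box is the minimal axis-aligned box containing every eyeball or
    optic-nerve voxel, expanded by ``margin_voxels`` on each face and
    clamped to the grid.  Geometry is unchanged (no resampling).
    """
    if volume.labels is None:
        raise ValueError("crop_to_roi requires a label volume")
    fg = np.argwhere(volume.labels > 0)
    if fg.size == 0:
        raise ValueError("no foreground labels to crop to")
    lo = np.maximum(fg.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(fg.max(axis=0) + margin_voxels + 1, volume.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return LabeledVolume(
        intensities=volume.intensities[sl].copy(),
        labels=volume.labels[sl].copy(),
        geometry=volume.geometry, side=volume.side, subject_id=volume.subject_id,
    )


def extract_axial_slices(volume: LabeledVolume) -> list[SliceSample]:
    """Unstack a volume into ordered axial SliceSamples (index ascending)."""
    n = volume.n_slices
    return [
        SliceSample(
            image=volume.intensities[k],
            mask=None if volume.labels is None else volume.labels[k],
            slice_index=k, n_slices=n, geometry=volume.geometry,
            side=volume.side, subject_id=volume.subject_id,
        )
        for k in range(n)
    ]


def stack_slices(samples: Sequence[SliceSample]) -> LabeledVolume:
    """Inverse of :func:`extract_axial_slices`."""
    if not samples:
        raise ValueError("no slices to stack")
    order = sorted(samples, key=lambda s: s.slice_index)
    idx = [s.slice_index for s in order]
    if idx != list(range(len(order))):
        raise ValueError(f"slice indices {idx} are not a contiguous 0-based range")
    first = order[0]
    intensities = np.stack([s.image for s in order], axis=0)
    labels = None
    if first.mask is not None:
        labels = np.stack([s.mask for s in order], axis=0)
    return LabeledVolume(intensities=intensities, labels=labels,
                         geometry=first.geometry, side=first.side,
                         subject_id=first.subject_id)


def export_slice_png(sample: SliceSample, path: os.PathLike | str) -> None:
    """Write a side-by-side image/mask PNG for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 2 if sample.mask is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(3 * ncols, 3))
    axes = np.atleast_1d(axes)
    axes[0].imshow(sample.image, cmap="gray")
    axes[0].set_title(f"slice {sample.slice_index}")
    if sample.mask is not None:
        axes[1].imshow(sample.mask, vmin=0, vmax=2, cmap="viridis")
        axes[1].set_title("labels")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
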