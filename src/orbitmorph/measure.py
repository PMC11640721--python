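"""Clinical morphometry from 3-class label volumes.

Three quantities are computed from a segmented orbit stack:

* **Eyeball volume** — summed per-slice eyeball areas times the slice
  thickness, ``V = sum_i Area_i * sz``, reported in cm3.
* **Optic nerve sheath diameter (ONSD)** — the mean of the longest and
  shortest caliper (Feret) diameters of the nerve cross section,
  ``ONSD_i = (D_longest + D_shortest) / 2``, measured on the first and the
  immediately following nerve-bearing slice, reported in cm.
* **Apex-to-eyeball distance (AED)** — the 3D Euclidean distance between
  the nerve-region centroids of the first and last nerve-bearing slices,
  ``sqrt(dx^2 + dy^2 + (n * sz)^2)`` with ``n`` the slice-index gap,
  reported in cm.

All internal geometry is in mm; conversions to cm3 / cm happen only at
the reporting boundary.  "First" slice means lowest stored slice index;
pass ``reverse_slices=True`` if the acquisition order runs the other way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label

from .io_prep import EYEBALL, OPTIC_NERVE, LabeledVolume, VoxelGeometry


@dataclass(frozen=True)
class DiameterPair:
    """Longest and shortest caliper diameters of a planar region, in mm."""

    longest: float
    shortest: float

    def __post_init__(self) -> None:
        if not (self.longest >= self.shortest > 0):
            raise ValueError(f"need longest >= shortest > 0, got {self}")

    @property
    def mean(self) -> float:
        return (self.longest + self.shortest) / 2.0


@dataclass(frozen=True)
class OnsdResult:
    side: str
    first_cm: float
    second_cm: Optional[float]
    first_slice: int
    second_slice: Optional[int]


@dataclass(frozen=True)
class AedEndpoints:
    start_xy_mm: tuple[float, float]
    end_xy_mm: tuple[float, float]
    n_between: int
    thickness_mm: float


@dataclass
class MeasurementRecord:
    """Per-orbit measurement row with provenance."""

    subject_id: str
    side: str
    source: Literal["truth", "predicted", "ophthalmologist"]
    volume_cm3: float
    onsd_first_cm: Optional[float] = None
    onsd_second_cm: Optional[float] = None
    aed_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.volume_cm3 < 0:
            raise ValueError("volume must be >= 0")
        if self.aed_cm is not None and self.aed_cm < 0:
            raise ValueError("aed must be >= 0")


# ---------------------------------------------------------------------------
# mask-geometry primitives


def slice_area(mask: np.ndarray, geometry: VoxelGeometry) -> float:
    """Area of a binary slice in mm2 (pixel count x sx x sy)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("slice_area expects a 2D mask")
    return float(np.count_nonzero(mask)) * geometry.sx * geometry.sy


def eyeball_volume(labels: np.ndarray, geometry: VoxelGeometry) -> float:
    """Eyeball volume in cm3: summed slice areas times slice thickness."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("eyeball_volume expects a 3D label grid")
    n_vox = int(np.count_nonzero(labels == EYEBALL))
    if n_vox == 0:
        warnings.warn("no eyeball voxels found; volume is 0", stacklevel=2)
    return n_vox * geometry.voxel_volume_mm3 / 1000.0


def _largest_component_2d(mask: np.ndarray) -> np.ndarray:
    lab = cc_label(mask, connectivity=2)
    if lab.max() <= 1:
        return mask.astype(bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _pixel_points_mm(mask: np.ndarray, geometry: VoxelGeometry) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols * geometry.sx, rows * geometry.sy])


def feret_diameters(mask: np.ndarray, geometry: VoxelGeometry) -> DiameterPair:
    """Longest/shortest caliper diameters of the largest component, in mm.

    Diameters are measured on the half-level (marching-squares) boundary
    of the region, i.e. the sub-pixel contour midway between foreground
    and background pixel centers — the same boundary convention as
    skimage's region properties.  The longest diameter is the maximum
    pairwise distance between convex-hull vertices of that contour; the
    shortest is the minimum width over hull-edge support directions.
    Both are floored at one in-plane pixel spacing so degenerate regions
    still yield a valid pair.
    """
    from skimage.measure import find_contours

    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("feret_diameters expects a 2D mask")
    if not mask.any():
        raise ValueError("empty mask has no diameters")
    comp = _largest_component_2d(mask)
    padded = np.pad(comp, 1).astype(float)  # keep border contours closed
    contours = find_contours(padded, 0.5)
    rc = np.vstack(contours) - 1.0  # back to unpadded pixel coordinates
    pts = np.column_stack([rc[:, 1] * geometry.sx, rc[:, 0] * geometry.sy])
    floor = geometry.in_plane_max
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # degenerate contour
        verts = pts
    # max caliper: max pairwise distance over hull vertices
    diff = verts[:, None, :] - verts[None, :, :]
    longest = float(np.sqrt((diff ** 2).sum(-1)).max())
    # min caliper: min over edge directions of the extent perpendicular to
    # the edge (valid because the minimum width is attained flush with an
    # edge of the convex hull)
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    ok = lengths > 0
    if ok.any():
        normals = np.column_stack([-edges[ok, 1], edges[ok, 0]]) / lengths[ok, None]
        proj = verts @ normals.T  # (n_verts, n_edges)
        shortest = float((proj.max(axis=0) - proj.min(axis=0)).min())
    else:
        shortest = 0.0
    longest = max(longest, floor)
    shortest = max(shortest, floor)
    return DiameterPair(longest=max(longest, shortest), shortest=min(longest, shortest))


def nerve_centroid(mask: np.ndarray, geometry: VoxelGeometry) -> tuple[float, float]:
    """Centroid (x, y) in mm of the largest component of a nerve slice."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    pts = _pixel_points_mm(_largest_component_2d(mask), geometry)
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


# ---------------------------------------------------------------------------
# clinical measures


def _nerve_slices(labels: np.ndarray, reverse_slices: bool) -> list[int]:
    idx = [k for k in range(labels.shape[0]) if (labels[k] == OPTIC_NERVE).any()]
    if not idx:
        raise ValueError("no optic-nerve voxels in the volume")
    return idx[::-1] if reverse_slices else idx


def onsd(labels: np.ndarray, geometry: VoxelGeometry, side: str = "unsplit",
         reverse_slices: bool = False) -> OnsdResult:
    """ONSD on the first two nerve-bearing slices, in cm.

    The first value is measured on the first slice (in scan order) where
    the nerve appears; the second on the immediately consecutive slice, or
    missing if the nerve is absent there.
    """
    labels = np.asarray(labels)
    idx = _nerve_slices(labels, reverse_slices)
    first = idx[0]
    step = -1 if reverse_slices else 1
    d1 = feret_diameters(labels[first] == OPTIC_NERVE, geometry)
    second = first + step
    second_val: Optional[float] = None
    second_idx: Optional[int] = None
    if 0 <= second < labels.shape[0] and (labels[second] == OPTIC_NERVE).any():
        d2 = feret_diameters(labels[second] == OPTIC_NERVE, geometry)
        second_val = d2.mean / 10.0
        second_idx = second
    return OnsdResult(side=side, first_cm=d1.mean / 10.0, second_cm=second_val,
                      first_slice=first, second_slice=second_idx)


def aed_endpoints(labels: np.ndarray, geometry: VoxelGeometry,
                  reverse_slices: bool = False) -> AedEndpoints:
    """Nerve centroids on the first and last nerve-bearing slices."""
    labels = np.asarray(labels)
    idx = _nerve_slices(labels, reverse_slices)
    start, end = idx[0], idx[-1]
    c1 = nerve_centroid(labels[start] == OPTIC_NERVE, geometry)
    c2 = nerve_centroid(labels[end] == OPTIC_NERVE, geometry)
    return AedEndpoints(start_xy_mm=c1, end_xy_mm=c2,
                        n_between=abs(end - start), thickness_mm=geometry.sz)


def aed(labels: np.ndarray, geometry: VoxelGeometry, side: str = "unsplit",
        reverse_slices: bool = False) -> float:
    """Apex-to-eyeball distance in cm (3D centroid-to-centroid)."""
    ep = aed_endpoints(labels, geometry, reverse_slices)
    dx = ep.end_xy_mm[0] - ep.start_xy_mm[0]
    dy = ep.end_xy_mm[1] - ep.start_xy_mm[1]
    return math.sqrt(dx * dx + dy * dy + (ep.n_between * ep.thickness_mm) ** 2) / 10.0


def clean_prediction(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest 3D 26-connected component of each structure.

    Model predictions can contain spurious islands, which would corrupt
    centroid and diameter measurements; ground-truth masks do not need
    this and should be measured as-is.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    for cls in (EYEBALL, OPTIC_NERVE):
        mask = labels == cls
        if not mask.any():
            continue
        lab = cc_label(mask, connectivity=3)
        if lab.max() <= 1:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        out[mask & (lab != sizes.argmax())] = 0
    return out


def measure_volume(volume: LabeledVolume, source: str = "truth",
                   clean: bool = False,
                   reverse_slices: bool = False) -> MeasurementRecord:
    """All three measures for one orbit volume, as a MeasurementRecord.

    ``clean=True`` applies largest-component cleanup first (recommended
    for predicted masks).  ONSD/AED are left missing when the volume has
    no nerve voxels.
    """
    if volume.labels is None:
        raise ValueError("measure_volume requires labels")
    labels = clean_prediction(volume.labels) if clean else volume.labels
    vol = eyeball_volume(labels, volume.geometry) if (labels == EYEBALL).any() else 0.0
    rec = MeasurementRecord(subject_id=volume.subject_id, side=volume.side,
                            source=source, volume_cm3=vol)
    if (labels == OPTIC_NERVE).any():
        o = onsd(labels, volume.geometry, volume.side, reverse_slices)
        rec.onsd_first_cm = o.first_cm
        rec.onsd_second_cm = o.second_cm
        rec.aed_cm = aed(labels, volume.geometry, volume.side, reverse_slices)
    return rec


def records_to_frame(records) -> "pandas.DataFrame":  # noqa: F821
    """Stack MeasurementRecords into a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])
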