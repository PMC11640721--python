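"""Synthetic orbit phantoms with analytic ground truth.

Each phantom is a per-orbit cropped axial stack holding an approximately
spherical eyeball and a thin, tapering, elliptical-cross-section optic
nerve tube that runs through the posterior slices to the orbital apex.
Because the shapes are analytic, the eyeball volume, the nerve diameter
profile and the apex-to-eyeball distance are known exactly, so every
downstream stage (segmentation, measurement, agreement statistics) can be
tested without clinical data.

Voxel class membership is decided at voxel centers (x = col*sx, y = row*sy,
z = slice*sz); where the eyeball and the nerve would overlap the eyeball
takes precedence, and the default geometry keeps them disjoint along z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_prep import (BACKGROUND, EYEBALL, OPTIC_NERVE, LabeledVolume,
                      VoxelGeometry)

DEFAULT_GEOMETRY = VoxelGeometry(sx=0.5, sy=0.5, sz=3.0)

#: class mean intensities (background, eyeball, nerve) in CT-like units.
#: Eyeball and nerve are deliberately close relative to the default noise
#: so that intensity alone does not separate them and slice position
#: carries real information.
DEFAULT_INTENSITY_MEANS = (0.0, 100.0, 85.0)
DEFAULT_NOISE_SD = 15.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full analytic description of one orbit phantom.

    Parameters
    ----------
    grid_shape:
        Voxel counts ``(nx, ny, nz)``.
    eyeball_center:
        Sphere center ``(x, y, z)`` in mm.
    eyeball_radius:
        Sphere radius in mm.
    nerve_start_slice, nerve_end_slice:
        First and last slice indices containing the nerve tube.
    nerve_path:
        Per-slice in-plane centroid offsets ``(dx, dy)`` in mm relative to
        the eyeball center, one entry per nerve slice.
    nerve_diameter_profile:
        Per-slice ``(long_axis, short_axis)`` diameters in mm.
    nerve_rotation_deg:
        Optional per-slice in-plane rotation of the elliptical cross
        section (degrees); defaults to axis-aligned.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    eyeball_center: tuple[float, float, float] = (16.0, 16.0, 12.0)
    eyeball_radius: float = 12.0
    nerve_start_slice: int = 9
    nerve_end_slice: int = 11
    nerve_path: tuple[tuple[float, float], ...] = ((0.0, 0.0),) * 3
    nerve_diameter_profile: tuple[tuple[float, float], ...] = ((5.0, 4.0),) * 3
    nerve_rotation_deg: tuple[float, ...] | None = None
    intensity_means: tuple[float, float, float] = DEFAULT_INTENSITY_MEANS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid_shape
        g = self.geometry
        cx, cy, cz = self.eyeball_center
        r = self.eyeball_radius
        if r <= 0:
            raise ValueError("eyeball_radius must be positive")
        extents = ((nx - 1) * g.sx, (ny - 1) * g.sy, (nz - 1) * g.sz)
        for c, ext, name in zip((cx, cy, cz), extents, "xyz"):
            if c - r < 0 or c + r > ext:
                raise ValueError(
                    f"eyeball sphere leaves the grid along {name}: "
                    f"center {c} mm, radius {r} mm, extent {ext} mm"
                )
        if self.nerve_end_slice < self.nerve_start_slice:
            raise ValueError("nerve_end_slice must be >= nerve_start_slice")
        if not (0 <= self.nerve_start_slice and self.nerve_end_slice < nz):
            raise ValueError("nerve slice range outside the grid")
        n_nerve = self.nerve_end_slice - self.nerve_start_slice + 1
        if len(self.nerve_path) != n_nerve:
            raise ValueError(f"nerve_path needs {n_nerve} entries, got {len(self.nerve_path)}")
        if len(self.nerve_diameter_profile) != n_nerve:
            raise ValueError(
                f"nerve_diameter_profile needs {n_nerve} entries, "
                f"got {len(self.nerve_diameter_profile)}")
        floor = 2.0 * g.in_plane_max
        for long_ax, short_ax in self.nerve_diameter_profile:
            if short_ax <= floor or long_ax < short_ax:
                raise ValueError(
                    f"nerve diameters ({long_ax}, {short_ax}) mm must satisfy "
                    f"long >= short > {floor} mm (2x in-plane spacing)")
        if self.nerve_rotation_deg is not None and len(self.nerve_rotation_deg) != n_nerve:
            raise ValueError("nerve_rotation_deg length mismatch")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_nerve_slices(self) -> int:
        return self.nerve_end_slice - self.nerve_start_slice + 1


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground-truth measurements for one phantom.

    Volumes in cm3, diameters and distances in cm, matching the reporting
    units of the measurement module.
    """

    analytic_volume_cm3: float
    analytic_onsd_first_cm: float
    analytic_onsd_second_cm: float | None
    analytic_aed_cm: float
    class_counts_per_slice: np.ndarray  # (nz, 3) voxel counts

    @classmethod
    def from_spec(cls, spec: PhantomSpec,
                  class_counts: np.ndarray) -> "PhantomTruth":
        vol = (4.0 / 3.0) * math.pi * spec.eyeball_radius ** 3 / 1000.0
        prof = spec.nerve_diameter_profile
        onsd1 = (prof[0][0] + prof[0][1]) / 2.0 / 10.0
        onsd2 = (prof[1][0] + prof[1][1]) / 2.0 / 10.0 if len(prof) > 1 else None
        dx = spec.nerve_path[-1][0] - spec.nerve_path[0][0]
        dy = spec.nerve_path[-1][1] - spec.nerve_path[0][1]
        n = spec.nerve_end_slice - spec.nerve_start_slice
        aed = math.sqrt(dx * dx + dy * dy + (n * spec.geometry.sz) ** 2) / 10.0
        return cls(vol, onsd1, onsd2, aed, class_counts)


def make_phantom(spec: PhantomSpec, side: str = "unsplit",
                 subject_id: str = "phantom") -> tuple[LabeledVolume, PhantomTruth]:
    """Voxelize a phantom spec into intensity + label volumes.

    Labels are assigned by voxel-center membership in the analytic shapes;
    intensities are the per-class means plus seeded Gaussian noise.  The
    same spec (same seed) always produces bit-identical output.
    """
    nx, ny, nz = spec.grid_shape
    g = spec.geometry
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)

    xs = np.arange(nx) * g.sx
    ys = np.arange(ny) * g.sy
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    cx, cy, cz = spec.eyeball_center
    r2 = spec.eyeball_radius ** 2

    for k in range(nz):
        z = k * g.sz
        dz2 = (z - cz) ** 2
        if dz2 <= r2:
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 + dz2 <= r2
            labels[k][inside] = EYEBALL

    for i, k in enumerate(range(spec.nerve_start_slice, spec.nerve_end_slice + 1)):
        ox, oy = spec.nerve_path[i]
        ecx, ecy = cx + ox, cy + oy
        a = spec.nerve_diameter_profile[i][0] / 2.0
        b = spec.nerve_diameter_profile[i][1] / 2.0
        theta = 0.0
        if spec.nerve_rotation_deg is not None:
            theta = math.radians(spec.nerve_rotation_deg[i])
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - ecx) * ct + (yy - ecy) * st
        v = -(xx - ecx) * st + (yy - ecy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        sl = labels[k]
        sl[inside & (sl == BACKGROUND)] = OPTIC_NERVE  # eyeball takes precedence

    means = np.asarray(spec.intensity_means, dtype=np.float32)
    intensities = means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensities = intensities + rng.normal(
            0.0, spec.noise_sd, size=intensities.shape).astype(np.float32)
    intensities = intensities.astype(np.float32)

    counts = np.zeros((nz, 3), dtype=np.int64)
    for c in (BACKGROUND, EYEBALL, OPTIC_NERVE):
        counts[:, c] = (labels == c).sum(axis=(1, 2))

    volume = LabeledVolume(intensities=intensities, labels=labels,
                           geometry=g, side=side, subject_id=subject_id)
    return volume, PhantomTruth.from_spec(spec, counts)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for cohort phantom parameters.

    Defaults emulate adult orbits: eyeball radius 11.3-13.3 mm (volume
    about 6-10 cm3), nerve starting diameter 4-6 mm tapering to ~60% at
    the apex, ellipse axis ratio 1.2-1.6, and a few mm of in-plane drift
    from globe to apex.
    """

    eyeball_radius_mm: tuple[float, float] = (11.3, 13.3)
    center_jitter_mm: tuple[float, float] = (-1.0, 1.0)
    nerve_diameter_mm: tuple[float, float] = (4.0, 6.0)
    nerve_axis_ratio: tuple[float, float] = (1.2, 1.6)
    nerve_taper: tuple[float, float] = (0.55, 0.75)
    nerve_drift_mm: tuple[float, float] = (-4.0, 4.0)
    noise_sd: tuple[float, float] = (DEFAULT_NOISE_SD, DEFAULT_NOISE_SD)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.__dict__.items():
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


@dataclass
class CohortMember:
    """One orbit of a cohort subject, with its spec and analytic truth."""

    subject_id: str
    side: str
    sex: str
    age_group: str
    spec: PhantomSpec
    volume: LabeledVolume
    truth: PhantomTruth


def _draw(rng: np.random.Generator, rg: tuple[float, float]) -> float:
    lo, hi = rg
    return lo if lo == hi else float(rng.uniform(lo, hi))


def make_cohort(n_subjects: int,
                ranges: CohortRanges | None = None,
                seed: int = 0,
                grid_shape: tuple[int, int, int] = (64, 64, 12),
                geometry: VoxelGeometry = DEFAULT_GEOMETRY,
                intensity_means: tuple[float, float, float] = DEFAULT_INTENSITY_MEANS,
                ) -> list[CohortMember]:
    """Generate a seeded cohort of ``2 * n_subjects`` orbit phantoms.

    Both orbits of a subject share the subject id (and sex / age-group
    stratum labels); the left orbit mirrors the right orbit's drift so the
    pair is anatomically plausible but not identical.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    members: list[CohortMember] = []
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        age_group = "19-64" if rng.random() < 0.7 else "65+"
        radius = _draw(rng, ranges.eyeball_radius_mm)
        cx0 = (nx - 1) * geometry.sx / 2.0
        cy0 = (ny - 1) * geometry.sy / 2.0
        for side in ("right", "left"):
            cx = cx0 + _draw(rng, ranges.center_jitter_mm)
            cy = cy0 + _draw(rng, ranges.center_jitter_mm)
            cz = radius  # globe touches the first slice; apex slices stay free
            # nerve begins on the first slice clear of the globe
            start = int((cz + radius) // geometry.sz) + 1
            end = nz - 1
            n_sl = end - start + 1
            drift_x = _draw(rng, ranges.nerve_drift_mm)
            drift_y = _draw(rng, ranges.nerve_drift_mm)
            if side == "left":
                drift_x = -drift_x
            frac = np.linspace(0.0, 1.0, n_sl)
            path = tuple((float(drift_x * f), float(drift_y * f)) for f in frac)
            d0 = _draw(rng, ranges.nerve_diameter_mm)
            ratio = _draw(rng, ranges.nerve_axis_ratio)
            taper = _draw(rng, ranges.nerve_taper)
            scale = np.linspace(1.0, taper, n_sl)
            floor = 2.0 * geometry.in_plane_max + 0.25
            profile = tuple(
                (max(float(d0 * ratio * f), floor * ratio),
                 max(float(d0 * f), floor))
                for f in scale
            )
            spec = PhantomSpec(
                grid_shape=grid_shape, geometry=geometry,
                eyeball_center=(cx, cy, cz), eyeball_radius=radius,
                nerve_start_slice=start, nerve_end_slice=end,
                nerve_path=path, nerve_diameter_profile=profile,
                intensity_means=intensity_means,
                noise_sd=_draw(rng, ranges.noise_sd),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, truth = make_phantom(spec, side=side, subject_id=sid)
            members.append(CohortMember(sid, side, sex, age_group, spec, vol, truth))
    return members
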