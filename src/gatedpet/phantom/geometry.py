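"""Voxelized beating-LV phantom geometry.

The left ventricle is modeled as a thick-walled prolate half-ellipsoid
shell: the cavity is the half-ellipsoid

    x^2 + y^2 <= a^2 (1 - (z/c)^2),   -c <= z <= 0,       c = ratio * a,

with the apex at z = -c and the basal plane at z = 0.  The myocardium is
the shell between the inner (a, c) and outer (a + w, c + w) half-
ellipsoids (wall thickness w along the axes), closed at the base by a flat
myocardial cap of configurable thickness over the basal disk, so that the
cavity is fully enclosed and every ray from an interior point crosses
myocardium.  Setting ``cap_thickness=0`` leaves the base open (no basal
wall), which exercises the segmentation stage's estimated-plane cap path.

Activity: myocardium at ``myocardial_activity``; cavity and exterior at
``background_ratio`` times that.  Partial-volume behaviour of the scanner
is emulated by an isotropic Gaussian blur of ``psf_fwhm``.

Voxelization is anti-aliased: each voxel's myocardium/cavity occupancy
fraction is computed on a ``supersample``^3 sub-grid, so voxel-summed
cavity volume converges to the analytic value as the voxel shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import DataError

__all__ = [
    "PhantomConfig", "PhantomFrame", "voxelize_frame",
    "cavity_semi_axes", "analytic_cavity_volume",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def cavity_semi_axes(volume_ul: float, long_axis_ratio: float) -> Tuple[float, float]:
    """Semi-axes (a, c) of a half-ellipsoid cavity of the given volume.

    V = (2/3) pi a^2 c with c = ratio * a  =>  a = (3V / (2 pi ratio))^(1/3).
    1 µL = 1 mm^3.
    """
    if volume_ul <= 0:
        raise DataError("cavity volume must be positive")
    a = (3.0 * volume_ul / (2.0 * np.pi * long_axis_ratio)) ** (1.0 / 3.0)
    return a, long_axis_ratio * a


def analytic_cavity_volume(a: float, c: float) -> float:
    """Volume of the half-ellipsoid cavity, µL."""
    return (2.0 / 3.0) * np.pi * a * a * c


@dataclass(frozen=True)
class PhantomConfig:
    """Static phantom + idealized-scanner configuration (units mm, µL)."""

    wall_thickness: float = 2.0
    long_axis_ratio: float = 1.8
    myocardial_activity: float = 1.0
    background_ratio: float = 0.1
    psf_fwhm: float = 0.8
    voxel_size: float = 1.0
    grid_shape: Tuple[int, int, int] = (24, 24, 24)
    total_counts: float = 5.0e6
    cap_thickness: Optional[float] = None  # None -> wall_thickness; 0 -> open base
    origin: Optional[Tuple[float, float, float]] = None  # mm corner of voxel (0,0,0)
    supersample: int = 2

    def __post_init__(self):
        if self.wall_thickness <= 0:
            raise DataError("wall_thickness must be positive")
        if not (0.0 <= self.background_ratio < 1.0):
            raise DataError("background_ratio must be in [0, 1)")
        if self.voxel_size <= 0:
            raise DataError("voxel_size must be positive")
        if self.long_axis_ratio <= 0:
            raise DataError("long_axis_ratio must be positive")
        if self.supersample < 1:
            raise DataError("supersample must be >= 1")

    @property
    def cap(self) -> float:
        return self.wall_thickness if self.cap_thickness is None else self.cap_thickness

    def grid_origin(self) -> np.ndarray:
        """Corner (mm) of voxel (0,0,0); defaults to centring the grid on 0."""
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        extent = np.asarray(self.grid_shape, float) * self.voxel_size
        return -extent / 2.0

    def voxel_centers(self):
        """1-D center-coordinate arrays (x, y, z) in mm."""
        o = self.grid_origin()
        return tuple(
            o[i] + (np.arange(self.grid_shape[i]) + 0.5) * self.voxel_size
            for i in range(3))


@dataclass
class PhantomFrame:
    """One voxelized phantom frame plus its analytic ground truth."""

    activity: np.ndarray          # (nx, ny, nz) activity concentration
    cavity_fraction: np.ndarray   # per-voxel cavity occupancy in [0, 1]
    config: PhantomConfig
    cavity_volume: float          # analytic (pre-voxelization) cavity volume, µL
    semi_axes: Tuple[float, float]

    @property
    def voxel_volume(self) -> float:
        return self.config.voxel_size ** 3

    def cavity_volume_voxelized(self) -> float:
        """Voxel-summed cavity volume, µL (converges to the analytic value)."""
        return float(self.cavity_fraction.sum() * self.voxel_volume)


def _region_fractions(config: PhantomConfig, a: float, c: float):
    """Anti-aliased cavity and myocardium occupancy fractions per voxel."""
    s = config.supersample
    nx, ny, nz = config.grid_shape
    o = config.grid_origin()
    vs = config.voxel_size
    w = config.wall_thickness
    cap = config.cap

    def axis(n, o1):
        return o1 + (np.arange(n * s) + 0.5) * (vs / s)

    x = axis(nx, o[0])[:, None, None]
    y = axis(ny, o[1])[None, :, None]
    z = axis(nz, o[2])[None, None, :]

    rho2 = x * x + y * y
    inner = (z <= 0) & (z >= -c) & (rho2 <= a * a * (1.0 - (z / c) ** 2))
    ao, co = a + w, c + w
    outer = (z <= 0) & (z >= -co) & (rho2 <= ao * ao * (1.0 - (z / co) ** 2))
    myo = outer & ~inner
    if cap > 0:
        lid = (z > 0) & (z <= cap) & (rho2 <= ao * ao)
        myo = myo | lid

    def pool(m):
        return m.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))

    return pool(inner.astype(float)), pool(myo.astype(float))


def voxelize_frame(config: PhantomConfig, cavity_volume: float) -> PhantomFrame:
    """Voxelize one phase of the beating LV at the given cavity volume.

    The semi-axes are solved analytically from the volume (fixed wall
    thickness, fixed long-axis ratio), so the enclosed analytic cavity
    volume equals ``cavity_volume`` exactly; the analytic value is stored
    as frame metadata independent of the grid.
    """
    a, c = cavity_semi_axes(cavity_volume, config.long_axis_ratio)
    w = config.wall_thickness
    o = config.grid_origin()
    extent_hi = o + np.asarray(config.grid_shape, float) * config.voxel_size
    need_lo = np.array([-(a + w), -(a + w), -(c + w)])
    need_hi = np.array([a + w, a + w, config.cap])
    if np.any(need_lo < o) or np.any(need_hi > extent_hi):
        raise DataError(
            f"phantom (extent {need_lo} .. {need_hi} mm) exceeds grid "
            f"({o} .. {extent_hi} mm)")

    cav_frac, myo_frac = _region_fractions(config, a, c)
    bg = config.background_ratio * config.myocardial_activity
    activity = bg + (config.myocardial_activity - bg) * myo_frac
    if config.psf_fwhm > 0:
        sigma_vox = config.psf_fwhm * FWHM_TO_SIGMA / config.voxel_size
        activity = gaussian_filter(activity, sigma_vox, mode="nearest")
    return PhantomFrame(
        activity=activity, cavity_fraction=cav_frac, config=config,
        cavity_volume=float(cavity_volume), semi_axes=(a, c))
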