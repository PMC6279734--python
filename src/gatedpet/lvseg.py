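"""LV cavity volumetry from gated count images.

QGS-style count-based surface detection, built for rat-heart-sized
structures near scanner resolution:

1. ``upsample``: trilinear interpolation onto a 5x finer grid (the small
   rat LV spans only a handful of reconstructed voxels, so all later
   steps run on the magnified image).
2. ``find_lv_center``: one shared LV center from the gate-summed image --
   the intensity-weighted centroid of the largest connected component
   above half the 99th-percentile intensity (stabilises low-count gates).
3. ``detect_endocardium``: ~500 quasi-uniform rays from the center; along
   each ray a Gaussian is first fitted to the myocardial count peak
   (mid-myocardium at radius mu, width sigma, amplitude A, baseline b) to
   localise the wall and gate quality (R^2 >= 0.8, peak inside range).
   The endocardial radius then comes from a blur-aware wall model: a
   blurred-slab (erf-pair) profile

       full/2 * [erf((x - r_i)/(sqrt(2) s)) - erf((x - r_i - w)/(sqrt(2) s))] + b

   whose inner-edge parameter r_i is read off directly.  A pure Gaussian
   half-maximum offset (mu - sigma*sqrt(2 ln 2)) is exact only when the
   wall is thin relative to the blur; for a 2 mm wall at sub-mm FWHM the
   Gaussian underestimates the full myocardial amplitude and biases radii
   inward by ~0.1 mm, which alone busts a 5% volume budget for rat-sized
   ventricles.  When the erf-pair fit fails, the measured profile's inner
   crossing of the fitted half-maximum level b + A/2 (identical to the
   Gaussian offset for truly Gaussian walls) is the fallback.  Rays
   failing all quality gates are flagged and imputed from valid angular
   neighbours; basal-side rays that see no wall (open mitral plane) take
   the estimated base plane instead.
4. ``cavity_volume``: solid-angle-weighted cone sum V = sum dOmega/3 r^3
   (1 mm^3 = 1 uL), plus an analytic flat-cap term for the basal
   exclusion cone.

Everything is intensity-scale free: multiplying the image by a positive
constant leaves all radii, and hence all volumes, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .curves import VolumeCurve
from .errors import DataError, UnreliableGateError
from .gating import GatedImageSeries

__all__ = [
    "SegmentationConfig", "EndocardialSurface",
    "upsample", "find_lv_center", "detect_endocardium", "cavity_volume",
    "segment_series", "fibonacci_directions",
]

# ray status codes
WALL = 0        # valid Gaussian wall fit
PLANE = 1       # basal-side ray closed by the estimated base plane
IMPUTED = 2     # failed fit, radius imputed from valid neighbours
INVALID = 3     # failed fit, no imputation possible


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the volumetry stage (lengths in mm)."""

    upsample_factor: int = 5
    n_directions: int = 500
    basal_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    #: cone half-angle around the basal axis never ray-sampled; closed by
    #: an analytic flat cap at the estimated base plane
    basal_exclusion_deg: float = 30.0
    #: basal-side rays failing the wall fit within this angle of the axis
    #: are treated as crossing the open base plane rather than imputed
    open_base_deg: float = 65.0
    min_valid_fraction: float = 0.8
    rsq_min: float = 0.8
    #: profile sampling step as a fraction of the (fine) voxel size
    step_fraction: float = 0.5
    n_harmonics: int = 4


@dataclass
class EndocardialSurface:
    """Radial endocardial surface sampled over quasi-uniform directions."""

    center: np.ndarray           # mm
    directions: np.ndarray       # (N, 3) unit vectors (excluded cone removed)
    radii: np.ndarray            # mm
    status: np.ndarray           # per-direction code (WALL/PLANE/IMPUTED/INVALID)
    solid_angle: float           # dOmega per direction, sr
    base_height: float = 0.0     # center -> base plane distance h, mm
    excluded_cone_deg: float = 0.0
    basal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def valid_fraction(self) -> float:
        considered = self.status != PLANE
        if considered.sum() == 0:
            return 0.0
        return float((self.status[considered] == WALL).mean())


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def upsample(image: np.ndarray, factor: int = 5) -> np.ndarray:
    """Trilinear upsampling by an integer factor, total intensity preserved.

    Fine voxel centers sit at coarse fractional indices (j + 0.5)/f - 0.5;
    the result is rescaled so its sum matches the input (within float
    rounding), keeping count statistics interpretable.
    """
    if int(factor) != factor or factor < 1:
        raise DataError("upsample factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return image.astype(float, copy=True)
    coords = [
        (np.arange(n * factor) + 0.5) / factor - 0.5 for n in image.shape
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(image.astype(float), grid, order=1,
                                  mode="nearest")
    s_in, s_out = image.sum(), out.sum()
    if s_out > 0:
        out *= s_in / s_out
    return out


def find_lv_center(image: np.ndarray, voxel_size: float,
                   origin) -> np.ndarray:
    """Intensity-weighted centroid of the brightest connected structure (mm).

    Mask: voxels above 50% of the 99th-percentile intensity; only the
    largest connected component contributes.
    """
    if image.size == 0 or image.max() <= 0:
        raise DataError("empty image: cannot locate LV center")
    thr = 0.5 * np.percentile(image, 99)
    mask = image > thr
    if not mask.any():
        raise DataError("empty mask: no voxels above the centering threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    w = np.where(mask, image, 0.0)
    idx = np.array(ndimage.center_of_mass(w))
    return np.asarray(origin, float) + (idx + 0.5) * voxel_size


def _gauss(x, A, mu, sigma, b):
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + b


def _gauss_jac(x, A, mu, sigma, b):
    e = np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))
    d = (x - mu) / sigma ** 2
    return np.stack([e, A * e * d, A * e * d * (x - mu) / sigma,
                     np.ones_like(x)], axis=1)


def _erf_pair(x, full, ri, w, s, b):
    """Blurred-slab wall model: inner edge ri, width w, blur sigma s."""
    from scipy.special import erf

    rt2 = np.sqrt(2.0)
    return full * 0.5 * (erf((x - ri) / (rt2 * s))
                         - erf((x - ri - w) / (rt2 * s))) + b


def _erf_pair_jac(x, full, ri, w, s, b):
    from scipy.special import erf

    rt2 = np.sqrt(2.0)
    u1 = (x - ri) / (rt2 * s)
    u2 = (x - ri - w) / (rt2 * s)
    e1, e2 = np.exp(-u1 ** 2), np.exp(-u2 ** 2)
    spi = np.sqrt(np.pi)
    d_full = 0.5 * (erf(u1) - erf(u2))
    d_ri = full / (np.sqrt(2.0 * np.pi) * s) * (e2 - e1)
    d_w = full / (np.sqrt(2.0 * np.pi) * s) * e2
    d_s = full / (spi * s) * (-u1 * e1 + u2 * e2)
    return np.stack([d_full, d_ri, d_w, d_s, np.ones_like(x)], axis=1)


def _ray_profile(image, voxel_size, origin, center, direction, step):
    """1-D intensity profile along a ray, trilinear-sampled; (r, values)."""
    origin = np.asarray(origin, float)
    hi = origin + np.asarray(image.shape) * voxel_size
    # distance to the grid boundary along this direction
    t_max = np.inf
    for ax in range(3):
        d = direction[ax]
        if d > 1e-12:
            t_max = min(t_max, (hi[ax] - center[ax]) / d)
        elif d < -1e-12:
            t_max = min(t_max, (origin[ax] - center[ax]) / d)
    r = np.arange(step, t_max - step, step)
    if len(r) < 8:
        return r, np.zeros(len(r))
    pts = center[None, :] + r[:, None] * direction[None, :]
    idx = (pts - origin) / voxel_size - 0.5
    vals = ndimage.map_coordinates(image, idx.T, order=1, mode="nearest")
    return r, vals


_FIT_HALF_WINDOW = 5.0  # mm of profile kept either side of the peak


def _peak_window(r, prof):
    """Slice the profile to +- _FIT_HALF_WINDOW around the (smoothed) peak."""
    if len(r) == 0:
        return r, prof
    i_pk = int(np.argmax(np.convolve(prof, np.ones(3) / 3.0, mode="same")))
    keep = np.abs(r - r[i_pk]) <= _FIT_HALF_WINDOW
    return r[keep], prof[keep]


def _fit_wall_peak(r, prof, rsq_min):
    """Gaussian fit to the dominant wall peak; (mu, sigma, A, b) or None."""
    if len(r) < 8 or not np.any(prof > 0):
        return None
    i_pk = int(np.argmax(prof))
    b0 = float(np.min(prof))
    A0 = float(prof[i_pk] - b0)
    if A0 <= 0:
        return None
    p0 = [A0, r[i_pk], max(2.0 * (r[1] - r[0]), 0.3), b0]
    try:
        popt, _ = curve_fit(_gauss, r, prof, p0=p0, jac=_gauss_jac, maxfev=2000)
    except Exception:
        return None
    A, mu, sigma, b = popt
    sigma = abs(sigma)
    if A <= 0 or not (r[0] <= mu <= r[-1]):
        return None
    fit = _gauss(r, *popt)
    ss_tot = float(np.sum((prof - prof.mean()) ** 2))
    if ss_tot <= 0:
        return None
    rsq = 1.0 - float(np.sum((prof - fit) ** 2)) / ss_tot
    if rsq < rsq_min:
        return None
    return float(mu), float(sigma), float(A), float(b)


def _refine_edge(r, prof, gauss_fit):
    """Endocardial radius from the erf-pair wall model (Gaussian-seeded).

    Returns None if the refinement fails or lands outside the profile;
    callers then fall back to the half-maximum crossing.
    """
    mu, sigma, A, b = gauss_fit
    p0 = [A, mu - max(1.0, sigma), max(2.0 * sigma, 1.0),
          max(0.5 * sigma, 0.15), b]
    try:
        popt, _ = curve_fit(_erf_pair, r, prof, p0=p0, jac=_erf_pair_jac,
                            maxfev=4000)
    except Exception:
        return None
    full, ri, w, s, _ = popt
    if full <= 0 or w <= 0 or not (r[0] < ri < r[-1]):
        return None
    if not (ri < mu < ri + abs(w)):   # peak must sit inside the slab
        return None
    return float(ri)


def _half_max_crossing(r, prof, mu, A, b):
    """Inner crossing of the half-maximum level, walking inward from mu."""
    half = b + 0.5 * A
    i = int(np.searchsorted(r, mu))
    i = min(max(i, 1), len(r) - 1)
    while i > 0 and prof[i - 1] > half:
        i -= 1
    if i == 0:
        return None
    y0, y1 = prof[i - 1], prof[i]
    if y1 == y0:
        return float(r[i])
    return float(r[i - 1] + (half - y0) * (r[i] - r[i - 1]) / (y1 - y0))


def detect_endocardium(image: np.ndarray, voxel_size: float, origin,
                       center, config: SegmentationConfig = SegmentationConfig(),
                       ) -> EndocardialSurface:
    """Radial Gaussian-fit endocardial surface detection.

    Raises :class:`UnreliableGateError` when fewer than
    ``config.min_valid_fraction`` of the non-basal rays yield a valid wall
    fit.
    """
    center = np.asarray(center, float)
    origin = np.asarray(origin, float)
    hi = origin + np.asarray(image.shape) * voxel_size
    if np.any(center < origin) or np.any(center > hi):
        raise DataError("center lies outside the image")
    axis = np.asarray(config.basal_axis, float)
    axis = axis / np.linalg.norm(axis)

    dirs_full = fibonacci_directions(config.n_directions)
    cos_excl = np.cos(np.deg2rad(config.basal_exclusion_deg))
    cos_open = np.cos(np.deg2rad(config.open_base_deg))
    cos_theta = dirs_full @ axis
    sampled = cos_theta < cos_excl
    dirs = dirs_full[sampled]
    cos_theta = cos_theta[sampled]
    d_omega = 4.0 * np.pi / config.n_directions

    step = config.step_fraction * voxel_size
    n = len(dirs)
    radii = np.zeros(n)
    status = np.full(n, INVALID, dtype=int)
    for i in range(n):
        r, prof = _ray_profile(image, voxel_size, origin, center, dirs[i], step)
        r, prof = _peak_window(r, prof)
        fit = _fit_wall_peak(r, prof, config.rsq_min)
        if fit is not None:
            mu, sigma, A, b = fit
            edge = _refine_edge(r, prof, fit)
            if edge is None:
                edge = _half_max_crossing(r, prof, mu, A, b)
            if edge is not None and edge > 0:
                radii[i] = edge
                status[i] = WALL
                continue
        if cos_theta[i] > cos_open:
            status[i] = PLANE

    wall = status == WALL
    if wall.sum() == 0:
        raise UnreliableGateError("no valid wall rays",
                                  valid_fraction=0.0)

    # base plane height: basal-most z-extent of the detected wall
    z_extent = radii[wall] * (dirs[wall] @ axis)
    h = float(np.percentile(z_extent, 98)) if np.any(z_extent > 0) else 0.0
    plane = status == PLANE
    if h > 0:
        radii[plane] = h / cos_theta[plane]
    else:
        status[plane] = INVALID

    # impute remaining failures from the nearest valid neighbours
    bad = status == INVALID
    for i in np.where(bad)[0]:
        sim = dirs[wall] @ dirs[i]
        k = min(6, wall.sum())
        nearest = np.argsort(sim)[-k:]
        radii[i] = float(np.median(radii[wall][nearest]))
        status[i] = IMPUTED

    surface = EndocardialSurface(
        center=center, directions=dirs, radii=radii, status=status,
        solid_angle=d_omega, base_height=h,
        excluded_cone_deg=config.basal_exclusion_deg, basal_axis=axis)
    if surface.valid_fraction < config.min_valid_fraction:
        raise UnreliableGateError(
            f"only {surface.valid_fraction:.0%} of rays produced a valid "
            f"wall fit (< {config.min_valid_fraction:.0%})",
            valid_fraction=surface.valid_fraction)
    return surface


def cavity_volume(surface: EndocardialSurface) -> float:
    """Solid-angle-weighted cone sum over the surface, in µL.

    V = sum_d (dOmega_d / 3) r_d^3 over sampled directions, plus the
    analytic flat-cap (cone-to-plane) volume pi/3 h^3 tan^2(theta_excl)
    for the basal exclusion cone.
    """
    good = surface.status != INVALID
    if good.sum() == 0:
        raise DataError("surface has no usable rays")
    v = float(np.sum(surface.radii[good] ** 3) * surface.solid_angle / 3.0)
    th = np.deg2rad(surface.excluded_cone_deg)
    if th > 0 and surface.base_height > 0:
        v += np.pi / 3.0 * surface.base_height ** 3 * np.tan(th) ** 2
    return v


def segment_series(series: GatedImageSeries,
                   config: SegmentationConfig = SegmentationConfig(),
                   ) -> Tuple[VolumeCurve, dict]:
    """Per-gate LV cavity volumes from a gated image series.

    Pipeline: upsample each gate 5x -> one shared center from the
    gate-summed image -> per-gate endocardial detection -> cone-sum
    volumes.  Returns the sampled volume curve (gate midpoints) plus a
    diagnostics dict; unreliable gates raise with the gate index.
    """
    f = config.upsample_factor
    fine_vs = series.voxel_size / f
    summed = upsample(series.data.sum(axis=0).astype(float), f)
    center = find_lv_center(summed, fine_vs, series.origin)

    volumes = np.zeros(series.n_gates)
    validity = []
    for g in range(series.n_gates):
        fine = upsample(series.data[g].astype(float), f)
        try:
            surf = detect_endocardium(fine, fine_vs, series.origin, center,
                                      config)
        except UnreliableGateError as exc:
            raise UnreliableGateError(
                f"gate {g}: {exc}", gate=g,
                valid_fraction=exc.valid_fraction) from exc
        volumes[g] = cavity_volume(surf)
        validity.append(surf.valid_fraction)

    curve = VolumeCurve(gate_times=series.gate_times(), volumes=volumes,
                        period=series.period_estimate)
    info = {"center_mm": center.tolist(),
            "valid_fraction_per_gate": validity}
    return curve, info
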