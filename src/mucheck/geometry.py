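"""Geometric measurements feeding the cuboid MU model.

Extracts, from a voxelized target and a relative-stopping-power grid, the four
scalars the model consumes: target volume, beam's-eye-view (BEV) projected
area, mean water-equivalent depth (WED) of the distal target surface, and the
range-shifter air gap.

Conventions
-----------
* Continuous coordinates in cm.  Voxel ``(i, j, k)`` occupies the half-open box
  ``origin + [i*s, (i+1)*s)`` per axis; arrays are indexed ``[x, y, z]``.
* Parallel-beam geometry: every ray shares the beam direction (divergence is
  neglected, consistent with a large effective source-axis distance).
* IEC-style angles: gantry 0 enters from the anterior (+y) side travelling
  along ``(0, -1, 0)``; gantry 90 along ``(-1, 0, 0)``; the couch rotates the
  patient frame about the y axis.
* The patient surface along a ray is the first crossing (coming from outside)
  into a voxel with rsp above ``surface_threshold`` (default 0.2, excludes
  air).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ValidationError

__all__ = [
    "VoxelMask",
    "DensityGrid",
    "BeamGeometry",
    "beam_direction",
    "mask_volume",
    "bev_projected_area",
    "water_equivalent_depth",
    "distal_surface_wed",
    "air_gap",
    "trace_rays",
    "RayTrace",
    "DistalSurface",
]

DEFAULT_SURFACE_THRESHOLD = 0.2
DEFAULT_SHIFTER_WET_CM = 4.1

_EPS = 1e-12


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} must be a finite 3-vector, got {x!r}")
    return v


@dataclass(frozen=True)
class VoxelMask:
    """Boolean occupancy of a target on a regular axis-aligned grid."""

    origin: np.ndarray
    spacing: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        object.__setattr__(self, "spacing", _as_vec3(self.spacing, "spacing"))
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValidationError("occupancy must be a 3-D array")
        object.__setattr__(self, "occupancy", occ.astype(bool))
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacings must be positive")

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world-coordinate corners of the occupied region."""
        idx = np.argwhere(self.occupancy)
        if idx.size == 0:
            raise GeometryError("mask is empty")
        lo = self.origin + idx.min(axis=0) * self.spacing
        hi = self.origin + (idx.max(axis=0) + 1) * self.spacing
        return lo, hi

    def centroid(self) -> np.ndarray:
        idx = np.argwhere(self.occupancy)
        if idx.size == 0:
            raise GeometryError("mask is empty")
        return self.origin + (idx.mean(axis=0) + 0.5) * self.spacing


@dataclass(frozen=True)
class DensityGrid:
    """Relative stopping power (water = 1) on a regular grid."""

    origin: np.ndarray
    spacing: np.ndarray
    rsp: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        object.__setattr__(self, "spacing", _as_vec3(self.spacing, "spacing"))
        rsp = np.asarray(self.rsp, dtype=float)
        if rsp.ndim != 3:
            raise ValidationError("rsp must be a 3-D array")
        if np.any(rsp < 0):
            raise ValidationError("rsp values must be >= 0")
        object.__setattr__(self, "rsp", rsp)
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacings must be positive")

    @property
    def shape(self) -> tuple:
        return self.rsp.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + np.array(self.shape) * self.spacing

    def contains(self, point) -> bool:
        p = _as_vec3(point, "point")
        return bool(np.all(p >= self.origin - _EPS) and np.all(p <= self.upper + _EPS))

    @classmethod
    def uniform_water(cls, origin, spacing, shape) -> "DensityGrid":
        return cls(origin, spacing, np.ones(tuple(shape), dtype=float))


@dataclass(frozen=True)
class BeamGeometry:
    """Beam orientation plus range-shifter configuration."""

    gantry_deg: float
    couch_deg: float
    isocenter: np.ndarray
    range_shifted: bool = False
    shifter_wet: float = DEFAULT_SHIFTER_WET_CM
    shifter_face_distance: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "isocenter", _as_vec3(self.isocenter, "isocenter"))
        if not np.isfinite(self.gantry_deg) or not np.isfinite(self.couch_deg):
            raise ValidationError("beam angles must be finite")
        if self.range_shifted and self.shifter_wet <= 0:
            raise ValidationError("shifter_wet must be > 0 for range-shifted beams")

    @property
    def direction(self) -> np.ndarray:
        return beam_direction(self.gantry_deg, self.couch_deg)


def beam_direction(gantry_deg: float, couch_deg: float) -> np.ndarray:
    """Unit vector from virtual source toward isocenter in the patient frame.

    ``(0, 0) -> (0, -1, 0)``; ``(90, 0) -> (-1, 0, 0)``.  The couch rotation
    turns the patient about the y axis, so the returned vector is
    ``Ry(-couch) @ Rz(-gantry) @ (0, -1, 0)``.
    """
    if not (np.isfinite(gantry_deg) and np.isfinite(couch_deg)):
        raise ValidationError("angles must be finite")
    g = np.deg2rad(gantry_deg % 360.0)
    c = np.deg2rad(couch_deg % 360.0)
    d = np.array(
        [
            -np.sin(g) * np.cos(c),
            -np.cos(g),
            -np.sin(g) * np.sin(c),
        ]
    )
    return d / np.linalg.norm(d)


def mask_volume(mask: VoxelMask) -> float:
    """Occupied-voxel count times voxel volume, cm^3."""
    n = int(np.count_nonzero(mask.occupancy))
    if n == 0:
        raise GeometryError("mask is empty: degenerate target")
    return n * mask.voxel_volume_cm3


# ---------------------------------------------------------------------------
# BEV ray bundle
# ---------------------------------------------------------------------------


def _unit(direction) -> np.ndarray:
    d = _as_vec3(direction, "direction")
    n = np.linalg.norm(d)
    if n < _EPS:
        raise ValidationError("direction must be non-zero")
    return d / n


def _bev_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u, v) spanning the plane orthogonal to d."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, e)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


@dataclass
class RayTrace:
    """Parallel ray bundle through a mask (and optionally a density grid).

    Rays are indexed by flattened BEV pixel; only metadata for all pixels plus
    per-ray crossing parameters are stored.  ``t`` is the arc length along the
    beam direction from each ray's origin point.
    """

    direction: np.ndarray
    u: np.ndarray
    v: np.ndarray
    pixel_cm: float
    pixel_u: np.ndarray  # (nu,) plane coordinates of pixel centers
    pixel_v: np.ndarray  # (nv,)
    origins: np.ndarray  # (nu*nv, 3) ray origin points (upstream of everything)
    hit: np.ndarray  # (nu*nv,) bool — ray intersects the mask
    t_entry: np.ndarray  # (n_hit,) estimated proximal mask-crossing t
    t_exit: np.ndarray  # (n_hit,) estimated distal mask-crossing t
    wed_entry: Optional[np.ndarray] = None  # (n_hit,) WED at proximal crossing
    wed_exit: Optional[np.ndarray] = None  # (n_hit,) WED at distal crossing
    step_cm: float = 0.0
    hit_weight: Optional[np.ndarray] = None  # (nu*nv,) area weights; 0.5 on exact boundaries

    @property
    def n_hit(self) -> int:
        return int(np.count_nonzero(self.hit))

    @property
    def area_cm2(self) -> float:
        if self.hit_weight is None:
            return self.n_hit * self.pixel_cm**2
        return float(self.hit_weight.sum()) * self.pixel_cm**2

    def exit_points(self) -> np.ndarray:
        return self.origins[self.hit] + self.t_exit[:, None] * self.direction


def trace_rays(
    mask: VoxelMask,
    direction,
    pixel_cm: float,
    density: Optional[DensityGrid] = None,
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
    chunk_rays: int = 2048,
) -> RayTrace:
    """March a parallel BEV ray bundle through ``mask`` (and ``density``).

    One ray per BEV pixel at ``pixel_cm`` resolution; sampling step along each
    ray is half the minimum voxel spacing, with crossings refined to half a
    step.  When ``density`` is given, per-ray water-equivalent depths of the
    proximal and distal mask crossings are accumulated with the same samples.
    """
    d = _unit(direction)
    min_sp = float(np.min(mask.spacing))
    if not (0 < pixel_cm <= min_sp + _EPS):
        raise GeometryError(
            f"pixel_cm={pixel_cm} undersamples the mask (min spacing {min_sp})"
        )
    if density is not None and not np.allclose(density.spacing, mask.spacing):
        raise ValidationError("density grid spacing must match the mask's")

    lo, hi = mask.bounding_box()
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    u, v = _bev_basis(d)
    pu = corners @ u
    pv = corners @ v
    # anchor pixel centers at half-pixel offsets from the grid origin's
    # projection: for axis-aligned beams they then interleave voxel faces,
    # so snapped target boundaries never land exactly on a pixel center
    ou, ov = float(mask.origin @ u), float(mask.origin @ v)

    def _axis(o, lo, hi):
        k0 = int(np.floor((lo - o) / pixel_cm)) - 1
        k1 = int(np.ceil((hi - o) / pixel_cm)) + 1
        return o + (np.arange(k0, k1) + 0.5) * pixel_cm

    pixel_u = _axis(ou, pu.min(), pu.max())
    pixel_v = _axis(ov, pv.min(), pv.max())
    nu, nv = pixel_u.size, pixel_v.size

    # t range must span the density grid (for WED) or at least the mask bbox
    if density is not None:
        glo, ghi = density.origin, density.upper
        gcorners = np.array(
            [[x, y, z] for x in (glo[0], ghi[0]) for y in (glo[1], ghi[1]) for z in (glo[2], ghi[2])]
        )
    else:
        gcorners = corners
    td = gcorners @ d
    h = 0.5 * min_sp
    t0 = float(td.min()) - h
    t1 = float(td.max()) + h
    n_t = int(np.ceil((t1 - t0) / h))
    ts = (np.arange(n_t) + 0.5) * h  # midpoint samples, ray origin at t0

    uu, vv = np.meshgrid(pixel_u, pixel_v, indexing="ij")
    origins = (
        uu.reshape(-1, 1) * u + vv.reshape(-1, 1) * v + t0 * d
    )
    n_rays = origins.shape[0]

    hit = np.zeros(n_rays, dtype=bool)
    vmax = np.zeros(n_rays)
    first = np.full(n_rays, -1, dtype=np.int64)
    last = np.full(n_rays, -1, dtype=np.int64)
    want_wed = density is not None
    if want_wed:
        surf = np.full(n_rays, -1, dtype=np.int64)
        cum_at_first = np.zeros(n_rays)
        cum_at_last = np.zeros(n_rays)

    # occupancy is sampled at voxel centers and interpolated trilinearly, so
    # the detected target boundary passes midway between the last occupied
    # and first empty voxel center (no half-voxel shadow inflation)
    occ_f = mask.occupancy.astype(np.float32)
    for s in range(0, n_rays, chunk_rays):
        sl = slice(s, min(s + chunk_rays, n_rays))
        pts = origins[sl, None, :] + ts[None, :, None] * d  # (m, n_t, 3)
        m_chunk, n_chunk = pts.shape[0], pts.shape[1]
        ic = ((pts - mask.origin) / mask.spacing - 0.5).reshape(-1, 3).T
        vals = map_coordinates(occ_f, ic, order=1, mode="constant", cval=0.0)
        vals = vals.reshape(m_chunk, n_chunk)
        vmax[sl] = vals.max(axis=1)
        occ_s = vals > 0.5
        any_hit = occ_s.any(axis=1)
        hit[sl] = any_hit
        f = np.argmax(occ_s, axis=1)
        l = n_t - 1 - np.argmax(occ_s[:, ::-1], axis=1)
        first[sl] = np.where(any_hit, f, -1)
        last[sl] = np.where(any_hit, l, -1)
        if want_wed:
            didx = np.floor((pts - density.origin) / density.spacing).astype(np.int64)
            dshape = np.array(density.shape)
            dinside = np.all((didx >= 0) & (didx < dshape), axis=-1)
            dic = np.clip(didx, 0, dshape - 1)
            rsp_s = np.where(
                dinside, density.rsp[dic[..., 0], dic[..., 1], dic[..., 2]], 0.0
            )
            above = rsp_s > surface_threshold
            has_surf = above.any(axis=1)
            sf = np.where(has_surf, np.argmax(above, axis=1), -1)
            surf[sl] = sf
            cum = np.cumsum(rsp_s, axis=1) * h  # integral up to and incl. sample k
            m = occ_s.shape[0]
            rows = np.arange(m)
            # integral of rsp over samples [surf .. k] = cum[k] - cum[surf-1]
            base = np.where(sf > 0, cum[rows, np.maximum(sf - 1, 0)], 0.0)
            base = np.where(sf > 0, base, 0.0)
            cum_at_last[sl] = np.where(any_hit, cum[rows, np.maximum(l, 0)] - base, 0.0)
            cum_at_first[sl] = np.where(
                any_hit & (f > 0), cum[rows, np.maximum(f - 1, 0)] - base, 0.0
            )
            cum_at_first[sl] = np.maximum(cum_at_first[sl], 0.0)

    hf = first[hit]
    hl = last[hit]
    t_entry = ts[hf] - 0.5 * h
    t_exit = ts[np.clip(hl, 0, n_t - 1)] + 0.5 * h
    # rays grazing the boundary exactly (interpolated occupancy peaks at 0.5,
    # e.g. a face aligned with pixel centers) carry half a pixel of area
    hit_weight = hit.astype(float)
    hit_weight[~hit & (np.abs(vmax - 0.5) <= 1e-6)] = 0.5
    tr = RayTrace(
        direction=d,
        u=u,
        v=v,
        pixel_cm=pixel_cm,
        pixel_u=pixel_u,
        pixel_v=pixel_v,
        origins=origins,
        hit=hit,
        hit_weight=hit_weight,
        t_entry=t_entry,
        t_exit=t_exit,
        step_cm=h,
    )
    if want_wed:
        tr.wed_exit = np.maximum(cum_at_last[hit], 0.0)
        tr.wed_entry = np.maximum(cum_at_first[hit], 0.0)
    return tr


def bev_projected_area(mask: VoxelMask, direction, pixel_cm: float) -> float:
    """Area (cm^2) of the union of occupied-voxel shadows orthogonal to the beam."""
    tr = trace_rays(mask, direction, pixel_cm)
    if tr.n_hit == 0:
        raise GeometryError("no BEV ray intersects the mask")
    return tr.area_cm2


# ---------------------------------------------------------------------------
# Exact single-ray WED (voxel traversal, analytic partial steps)
# ---------------------------------------------------------------------------


def water_equivalent_depth(
    point,
    direction,
    density: DensityGrid,
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> float:
    """Line integral of rsp from the patient surface down to ``point`` (cm).

    The ray runs back along ``-direction`` from ``point``; the surface is the
    first above-threshold crossing seen from outside.  Piecewise-constant rsp
    is integrated exactly per traversed voxel (no step error).
    """
    p = _as_vec3(point, "point")
    d = _unit(direction)
    if not density.contains(p):
        raise GeometryError("point lies outside the density grid")

    lo, hi = density.origin, density.upper
    # upstream exit parameter: r(s) = p - s*d, s >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = (p - lo) / d
        s2 = (p - hi) / d
    smax_axis = np.where(np.abs(d) > _EPS, np.maximum(s1, s2), np.inf)
    s_exit = float(np.min(smax_axis))
    if not np.isfinite(s_exit) or s_exit < 0:
        raise GeometryError("upstream ray leaves the grid immediately")

    start = p - s_exit * d  # on the grid boundary, march downstream toward p
    t_end = s_exit
    shape = np.array(density.shape)
    spacing = density.spacing
    iv = np.floor((start - density.origin) / spacing).astype(np.int64)
    iv = np.clip(iv, 0, shape - 1)
    step = np.where(d > 0, 1, -1)
    with np.errstate(divide="ignore"):
        t_delta = np.where(np.abs(d) > _EPS, spacing / np.abs(d), np.inf)
    next_bound = density.origin + (iv + (step > 0)) * spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t_max = np.where(np.abs(d) > _EPS, (next_bound - start) / d, np.inf)

    t = 0.0
    wed = 0.0
    found_surface = False
    rsp = density.rsp
    while t < t_end - 1e-12:
        t_next = float(np.min(t_max))
        seg_end = min(t_next, t_end)
        val = rsp[iv[0], iv[1], iv[2]]
        if not found_surface and val > surface_threshold:
            found_surface = True
        if found_surface:
            wed += val * (seg_end - t)
        t = seg_end
        if t >= t_end - 1e-12:
            break
        ax = int(np.argmin(t_max))
        iv[ax] += step[ax]
        if iv[ax] < 0 or iv[ax] >= shape[ax]:
            break
        t_max[ax] += t_delta[ax]

    if not found_surface:
        pi = np.clip(
            np.floor((p - density.origin) / spacing).astype(np.int64), 0, shape - 1
        )
        if rsp[pi[0], pi[1], pi[2]] > surface_threshold:
            return 0.0
        raise GeometryError(
            "ray exited the grid without crossing a patient surface "
            "(point appears to lie outside the patient)"
        )
    return float(wed)


@dataclass
class DistalSurface:
    mean_cm: float
    per_ray_cm: np.ndarray
    trace: RayTrace


def distal_surface_wed(
    mask: VoxelMask,
    density: DensityGrid,
    direction,
    pixel_cm: float,
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> DistalSurface:
    """Mean and per-ray WED of the most-downstream mask crossing in the BEV."""
    tr = trace_rays(
        mask, direction, pixel_cm, density=density, surface_threshold=surface_threshold
    )
    if tr.n_hit == 0:
        raise GeometryError("no BEV ray intersects the mask")
    per_ray = tr.wed_exit
    mean = float(np.mean(per_ray))
    if mean <= 0:
        raise GeometryError("distal surface WED is non-positive; check geometry")
    return DistalSurface(mean_cm=mean, per_ray_cm=per_ray, trace=tr)


def air_gap(
    density: DensityGrid,
    beam: BeamGeometry,
    mask: Optional[VoxelMask] = None,
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> float:
    """Central-axis distance (cm) from the shifter downstream face to the skin.

    Traverses voxels exactly, so for a flat-surface phantom the result equals
    the analytic axis distance.  ``mask`` is accepted for interface symmetry
    but the gap depends only on the beam axis and the density grid.
    """
    if not beam.range_shifted:
        raise GeometryError("air_gap is only defined for range-shifted beams")
    d = beam.direction
    face = beam.isocenter - beam.shifter_face_distance * d

    lo, hi = density.origin, density.upper
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - face) / d
        t2 = (hi - face) / d
    tmin = np.where(np.abs(d) > _EPS, np.minimum(t1, t2), -np.inf)
    tmax = np.where(np.abs(d) > _EPS, np.maximum(t1, t2), np.inf)
    off_axis = (np.abs(d) <= _EPS) & ((face < lo) | (face > hi))
    t_in = float(np.max(tmin))
    t_out = float(np.min(tmax))
    if np.any(off_axis) or t_in >= t_out or t_out < 0:
        raise GeometryError("central axis misses the density grid")

    t_start = max(t_in, 0.0)
    shape = np.array(density.shape)
    spacing = density.spacing
    p0 = face + (t_start + _EPS) * d
    iv = np.floor((p0 - density.origin) / spacing).astype(np.int64)
    iv = np.clip(iv, 0, shape - 1)
    if density.rsp[iv[0], iv[1], iv[2]] > surface_threshold:
        if t_start > 0.0:
            return t_start  # surface coincides with the grid entry face
        # face sits in material: on the very surface (gap 0) or truly inside?
        up = face - 10 * _EPS * d
        iu = np.floor((up - density.origin) / spacing).astype(np.int64)
        outside = np.any(iu < 0) or np.any(iu >= shape)
        if outside or density.rsp[iu[0], iu[1], iu[2]] <= surface_threshold:
            return 0.0
        raise GeometryError("shifter face lies inside the patient")
    step = np.where(d > 0, 1, -1)
    with np.errstate(divide="ignore"):
        t_delta = np.where(np.abs(d) > _EPS, spacing / np.abs(d), np.inf)
    next_bound = density.origin + (iv + (step > 0)) * spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t_max = np.where(np.abs(d) > _EPS, (next_bound - face) / d, np.inf)

    while True:
        t_next = float(np.min(t_max))
        if t_next > t_out + 1e-9:
            raise GeometryError("central axis exits the grid before a surface crossing")
        ax = int(np.argmin(t_max))
        iv[ax] += step[ax]
        if iv[ax] < 0 or iv[ax] >= shape[ax]:
            raise GeometryError("central axis exits the grid before a surface crossing")
        t_max[ax] += t_delta[ax]
        if density.rsp[iv[0], iv[1], iv[2]] > surface_threshold:
            t_surf = t_next
            break

    if t_surf < -1e-9:
        raise GeometryError("shifter face lies inside the patient")
    return float(max(t_surf, 0.0))
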