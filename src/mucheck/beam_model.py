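"""Analytic stand-in for a commissioned PBS beam model.

Provides everything the factor-based MU check needs to be exercised without a
treatment planning system: a smooth parametric pristine Bragg curve, an NNLS
spread-out-Bragg-peak (SOBP) flattener, a generator for self-consistent factor
tables (OF/DF/AGF), and a layer-by-layer toy dose engine that assigns
ground-truth MUs to synthetic voxelized cases.

The model is deliberately simple — Gaussian-broadened peak on a tilted
entrance plateau, Gaussian lateral spot kernels, per-ray SFUD flattening — and
makes no claim of matching any clinical beam line.  Its purpose is structural:
same table shapes, same reference conditions, same normalizations as the
factor model, so the secondary check can be validated end-to-end against an
independent "TPS".
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.special import erf

from .errors import GeometryError, InfeasibleError, ValidationError
from .factors import (
    FactorSet,
    FactorTable1D,
    FactorTable2D,
    ReferenceConditions,
)
from .geometry import (
    BeamGeometry,
    DensityGrid,
    VoxelMask,
    air_gap,
    trace_rays,
)

__all__ = [
    "ToyModelConfig",
    "PristineBragg",
    "SOBPPlan",
    "bragg_curve",
    "flatten_sobp",
    "lateral_sigma",
    "cuboid_output",
    "generate_factor_set",
    "CaseSpec",
    "SyntheticCase",
    "generate_case",
    "node_case_specs",
    "shaped_case_specs",
    "generate_bundle",
    "toy_ground_truth",
]

_R80_SHIFT = math.sqrt(2.0 * math.log(1.0 / 0.8))  # peak sits this many sigma proximal of R80


@dataclass(frozen=True)
class ToyModelConfig:
    """Parameters of the analytic beam model.

    ``range_min_cm``/``range_max_cm`` bound the clinical band of deliverable
    pristine ranges; the internal dose engine may use layers down to
    ``engine_min_range_cm`` when building shallow tables.
    """

    range_min_cm: float = 4.0
    range_max_cm: float = 32.0
    layer_spacing_cm: float = 0.2
    # pristine peak width (cm) grows linearly with range
    peak_sigma_intercept_cm: float = 0.10
    peak_sigma_slope: float = 0.003
    # entrance plateau relative to unit peak Gaussian
    entrance_amplitude: float = 0.06
    entrance_slope: float = 0.30
    # lateral spot sigma at the patient (cm): base + energy term + shifter terms
    sigma0_cm: float = 0.32
    sigma_energy_coeff_cm: float = 0.05
    shifter_sigma_cm: float = 0.08
    gap_sigma_coeff: float = 0.02  # cm of sigma per cm of air gap
    spot_spacing_cm: float = 0.5
    shifter_wet_cm: float = 4.1
    depth_step_cm: float = 0.02
    plateau_sample_cm: float = 0.05
    engine_min_range_cm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        positive = (
            "layer_spacing_cm",
            "peak_sigma_intercept_cm",
            "sigma0_cm",
            "spot_spacing_cm",
            "shifter_wet_cm",
            "depth_step_cm",
            "plateau_sample_cm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.gap_sigma_coeff <= 0:
            raise ValidationError(
                "gap_sigma_coeff must be > 0 (sigma must grow with air gap)"
            )
        if not (0 < self.range_min_cm < self.range_max_cm):
            raise ValidationError("need 0 < range_min_cm < range_max_cm")


def _peak_sigma(cfg: ToyModelConfig, range_cm) -> np.ndarray:
    return cfg.peak_sigma_intercept_cm + cfg.peak_sigma_slope * np.asarray(range_cm)


def _bragg_dose(z, range_cm, cfg: ToyModelConfig) -> np.ndarray:
    """Analytic pristine depth dose; ``range_cm`` is the 80% distal-falloff depth."""
    z = np.asarray(z, dtype=float)
    r = np.asarray(range_cm, dtype=float)
    sp = _peak_sigma(cfg, r)
    zp = r - _R80_SHIFT * sp
    gauss = np.exp(-((z - zp) ** 2) / (2.0 * sp**2))
    # entrance term, rolled off through the peak by a sigmoid
    arg = np.clip((z - zp) / (0.5 * sp), -60.0, 60.0)
    roll = 1.0 / (1.0 + np.exp(arg))
    entrance = cfg.entrance_amplitude * (1.0 + cfg.entrance_slope * z / np.maximum(zp, 1e-6))
    return gauss + np.where(z >= 0, entrance * roll, 0.0)


@dataclass(frozen=True)
class PristineBragg:
    """Sampled pristine Bragg curve; dose normalized to a unit peak Gaussian."""

    range_cm: float
    depth_axis: np.ndarray
    dose_per_mu: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose_per_mu, dtype=float)
        z = np.asarray(self.depth_axis, dtype=float)
        if d.shape != z.shape or d.ndim != 1:
            raise ValidationError("depth_axis and dose_per_mu must be matching 1-D arrays")
        if np.any(d < 0):
            raise ValidationError("dose must be >= 0")
        peak_z = z[int(np.argmax(d))]
        if abs(peak_z - self.range_cm) > 0.3:
            raise ValidationError(
                f"peak at {peak_z:.2f} cm is more than 0.3 cm from range {self.range_cm}"
            )
        tail = d[z >= self.range_cm + 1.5]
        if tail.size and np.max(tail) > 0.01 * np.max(d):
            raise ValidationError("distal dose does not fall below 1% of peak within 1.5 cm")
        object.__setattr__(self, "depth_axis", z)
        object.__setattr__(self, "dose_per_mu", d)


def bragg_curve(range_cm: float, config: ToyModelConfig = ToyModelConfig()) -> PristineBragg:
    """Sampled pristine curve for a clinical-band range (errors outside it)."""
    if not (config.range_min_cm <= range_cm <= config.range_max_cm):
        raise InfeasibleError(
            f"range {range_cm} cm outside the clinical band "
            f"[{config.range_min_cm}, {config.range_max_cm}]"
        )
    z = np.arange(0.0, range_cm + 2.0 + config.depth_step_cm, config.depth_step_cm)
    return PristineBragg(range_cm=float(range_cm), depth_axis=z, dose_per_mu=_bragg_dose(z, range_cm, config))


@dataclass(frozen=True)
class SOBPPlan:
    """Weighted pristine-peak stack flattened over a depth plateau."""

    ranges: np.ndarray
    weights: np.ndarray
    plateau: tuple  # (proximal_cm, distal_cm)
    flatness: float

    def __post_init__(self):
        r = np.asarray(self.ranges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape:
            raise ValidationError("ranges and weights must match")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        lo, hi = self.plateau
        if not (r.max() >= hi - 1e-9):
            raise ValidationError("plateau extends beyond the deepest layer")
        object.__setattr__(self, "ranges", r)
        object.__setattr__(self, "weights", w)

    def dose(self, z, config: ToyModelConfig) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.zeros_like(z)
        for r, w in zip(self.ranges, self.weights):
            if w > 0:
                out += w * _bragg_dose(z, r, config)
        return out


def _solve_kernel(
    cfg: ToyModelConfig,
    distal_cm: float,
    width_cm: float,
    min_layer_range_cm: float,
) -> SOBPPlan:
    """NNLS layer weights giving unit mean plateau dose on [distal-width, distal]."""
    dl = cfg.layer_spacing_cm
    proximal = distal_cm - width_cm
    if min_layer_range_cm > proximal + dl + 1e-9:
        raise InfeasibleError(
            f"SOBP width {width_cm} cm at range {distal_cm} cm needs layers below "
            f"the minimum available range {min_layer_range_cm} cm"
        )
    # layers peak inside the target: deepest at the distal range, shallowest
    # at (or just below, for off-grid widths) the proximal plateau edge
    r_lo = max(min_layer_range_cm, proximal - 0.6 * dl)
    n = int(math.floor((distal_cm - r_lo) / dl + 1e-9)) + 1
    ranges = distal_cm - dl * np.arange(n)
    if ranges.size == 0:
        raise InfeasibleError("no energy layers available")

    # the plateau cannot extend into the distal falloff: the nominal distal
    # range is the 80% point, so the fit window stops ~2 peak-sigma short
    edge = 2.0 * float(_peak_sigma(cfg, distal_cm))
    z_hi = max(distal_cm - edge, proximal + 0.5 * width_cm)
    n_z = max(5, int(round((z_hi - proximal) / cfg.plateau_sample_cm)) + 1)
    z = np.linspace(proximal, z_hi, n_z)
    a = _bragg_dose(z[:, None], ranges[None, :], cfg)
    # small ridge on the weights: keeps NNLS from parking free MU on layers
    # whose peaks fall outside the fit window
    lam = 0.05
    a_ext = np.vstack([a, lam * np.eye(ranges.size)])
    b_ext = np.concatenate([np.ones(n_z), np.zeros(ranges.size)])
    w, _ = nnls(a_ext, b_ext)
    dose = a @ w
    mean = float(np.mean(dose))
    if mean <= 0:
        raise InfeasibleError("SOBP optimization produced zero dose")
    w = w / mean
    dose = dose / mean
    flat = float(np.max(np.abs(dose - 1.0)))
    return SOBPPlan(ranges=ranges, weights=w, plateau=(proximal, distal_cm), flatness=flat)


def flatten_sobp(
    distal_range_cm: float,
    width_cm: float,
    config: ToyModelConfig = ToyModelConfig(),
) -> SOBPPlan:
    """Flatten an SOBP of the given width ending at ``distal_range_cm``.

    Deterministic (pure NNLS).  Raises :class:`InfeasibleError` when the width
    cannot be covered by layers inside the clinical band.
    """
    if not (config.range_min_cm <= distal_range_cm <= config.range_max_cm):
        raise InfeasibleError(
            f"distal range {distal_range_cm} outside "
            f"[{config.range_min_cm}, {config.range_max_cm}]"
        )
    if not (0 < width_cm < distal_range_cm):
        raise InfeasibleError("need 0 < width < distal range")
    return _solve_kernel(config, distal_range_cm, width_cm, config.range_min_cm)


# ---------------------------------------------------------------------------
# Lateral model and cuboid output
# ---------------------------------------------------------------------------


def lateral_sigma(
    cfg: ToyModelConfig,
    nominal_range_cm: float,
    range_shifted: bool = False,
    gap_cm: float = 1.0,
) -> float:
    """Spot sigma (cm) at the patient: energy-dependent, broadened by the shifter."""
    r = float(np.clip(nominal_range_cm, 1.0, cfg.range_max_cm))
    s = cfg.sigma0_cm + cfg.sigma_energy_coeff_cm * (cfg.range_max_cm - r) / (
        cfg.range_max_cm - cfg.range_min_cm
    )
    if range_shifted:
        s += cfg.shifter_sigma_cm + cfg.gap_sigma_coeff * float(gap_cm)
    return s


def _square_field_fraction(area_cm2: float, sigma_cm: float) -> float:
    """Central lateral-equilibrium fraction of a uniform square field."""
    half = 0.5 * math.sqrt(area_cm2)
    e = erf(half / (math.sqrt(2.0) * sigma_cm))
    return float(e * e)


def _cuboid_outputs(
    cfg: ToyModelConfig,
    areas_cm2: np.ndarray,
    width_cm: float,
    distal_wed_cm: float,
    range_shifted: bool,
    gap_cm: float,
    min_layer_range_cm: float,
) -> np.ndarray:
    """Vectorized-over-area cuboid output: one kernel serves every field size."""
    offset = cfg.shifter_wet_cm if range_shifted else 0.0
    plan = _solve_kernel(cfg, distal_wed_cm + offset, width_cm, min_layer_range_cm)
    z_eval = distal_wed_cm - 0.5 * width_cm + offset
    areas = np.atleast_1d(np.asarray(areas_cm2, dtype=float))
    dose = np.zeros_like(areas)
    for r, w in zip(plan.ranges, plan.weights):
        if w <= 0:
            continue
        sig = lateral_sigma(cfg, r, range_shifted, gap_cm)
        b = float(_bragg_dose(z_eval, r, cfg))
        frac = np.array([_square_field_fraction(a, sig) for a in areas])
        dose += w * b * frac
    mu = float(np.sum(plan.weights)) * areas / cfg.spot_spacing_cm**2
    return dose / mu


def cuboid_output(
    cfg: ToyModelConfig,
    area_cm2: float,
    width_cm: float,
    distal_wed_cm: float,
    range_shifted: bool = False,
    gap_cm: float = 1.0,
    min_layer_range_cm: Optional[float] = None,
) -> float:
    """Dose per MU (cGy/MU, model units) at the SOBP center of a uniform cuboid.

    The analytic fast path of the toy engine: every BEV pixel shares one SOBP
    kernel and the lateral sum reduces to an erf product.
    """
    if area_cm2 <= 0 or width_cm <= 0 or distal_wed_cm <= width_cm:
        raise ValidationError("need positive area/width and distal depth > width")
    mlr = cfg.engine_min_range_cm if min_layer_range_cm is None else min_layer_range_cm
    return float(_cuboid_outputs(cfg, np.array([area_cm2]), width_cm, distal_wed_cm, range_shifted, gap_cm, mlr)[0])


# dense at small areas where the ~1/area shape of the output curves makes
# linear interpolation error largest; includes all integer squares
DEFAULT_AREA_AXIS = tuple(
    np.unique(
        np.concatenate(
            [
                np.arange(4.0, 16.0, 1.0),
                np.arange(16.0, 36.0, 2.0),
                np.array([k * k for k in range(6, 16)], dtype=float),
                np.array([k * (k + 1) for k in range(6, 15)], dtype=float),
            ]
        )
    )
)
DEFAULT_WIDTH_AXIS = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
AGF_CUBE_DISTAL_CM = 10.0  # 125 cm^3 cube centered at 7.5 cm depth


def _df_width(cfg: ToyModelConfig, range_cm: float) -> float:
    """Cube width used at each DF node; the canonical 5 cm where feasible."""
    return min(5.0, max(0.5, range_cm - cfg.engine_min_range_cm))


def generate_factor_set(config: ToyModelConfig = ToyModelConfig()) -> FactorSet:
    """Build a self-consistent OF/DF/AGF factor set from the toy engine.

    * OF: cuboids spanning areas up to 225 cm^2 and widths up to 10 cm at the
      20 cm reference depth (15.9 cm phantom depth for range-shifted delivery,
      1 cm reference gap).
    * DF: translating a 125 cm^3 cube through water, normalized at 20 cm
      (narrower cubes stand in below ~6 cm where the full cube will not fit).
    * AGF: the same cube at 10 cm distal depth behind the shifter, gaps 0-10,
      normalized at 1 cm.
    """
    ref = ReferenceConditions(depth_cm=20.0, gap_cm=1.0, shifter_wet_cm=config.shifter_wet_cm)
    areas = np.array(DEFAULT_AREA_AXIS)
    widths = np.array(DEFAULT_WIDTH_AXIS)

    of_open = np.empty((areas.size, widths.size))
    of_shifted = np.empty_like(of_open)
    shifted_depth = ref.depth_cm - config.shifter_wet_cm
    mlr = config.engine_min_range_cm
    for j, w in enumerate(widths):
        of_open[:, j] = _cuboid_outputs(config, areas, w, ref.depth_cm, False, ref.gap_cm, mlr)
        of_shifted[:, j] = _cuboid_outputs(config, areas, w, shifted_depth, True, ref.gap_cm, mlr)

    df_axis = np.arange(config.range_min_cm, config.range_max_cm + 1e-9, 1.0)
    if not np.any(np.isclose(df_axis, ref.depth_cm)):
        df_axis = np.sort(np.append(df_axis, ref.depth_cm))
    df_vals = np.array(
        [cuboid_output(config, 25.0, _df_width(config, r), r, False) for r in df_axis]
    )
    df_vals /= df_vals[np.argmin(np.abs(df_axis - ref.depth_cm))]

    agf_axis = np.arange(0.0, 10.0 + 1e-9, 0.5)
    agf_vals = np.array(
        [
            cuboid_output(config, 25.0, 5.0, AGF_CUBE_DISTAL_CM, True, g)
            for g in agf_axis
        ]
    )
    agf_vals /= agf_vals[np.argmin(np.abs(agf_axis - ref.gap_cm))]

    return FactorSet(
        of_open=FactorTable2D(areas, widths, of_open),
        of_shifted=FactorTable2D(areas, widths, of_shifted),
        df=FactorTable1D(df_axis, df_vals),
        agf=FactorTable1D(agf_axis, agf_vals),
        reference=ref,
        calibration=1.0,
    )


# ---------------------------------------------------------------------------
# Synthetic cases and the full (per-ray) toy dose engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseSpec:
    """Recipe for one synthetic (target, beam) pair in a water phantom."""

    shape: str  # "cuboid" | "ellipsoid" | "blob"
    size_cm: tuple  # cuboid: full edge lengths (lateral, depth, lateral);
    #                 ellipsoid/blob: semi-axes in the same order
    distal_depth_cm: float  # depth of the distal-most target point below the surface
    gantry_deg: float = 0.0
    couch_deg: float = 0.0
    range_shifted: bool = False
    gap_cm: float = 1.0
    site_label: str = "synthetic"
    prescribed_dose_cgy: float = 200.0
    spacing_cm: float = 0.125
    blob_amplitude: float = 0.12
    beam_id: str = ""

    def __post_init__(self):
        if self.shape not in ("cuboid", "ellipsoid", "blob"):
            raise ValidationError(f"unknown shape {self.shape!r}")
        if len(self.size_cm) != 3 or any(s <= 0 for s in self.size_cm):
            raise ValidationError("size_cm must be three positive lengths")
        if self.distal_depth_cm <= 0:
            raise ValidationError("distal_depth_cm must be > 0")


@dataclass
class SyntheticCase:
    """A complete generated case with toy-engine ground truth."""

    mask: VoxelMask
    density: DensityGrid
    beam: BeamGeometry
    prescribed_dose_cgy: float
    mu_ground_truth: float
    site_label: str
    beam_id: str
    technique: str = "sfud"
    spec: Optional[CaseSpec] = None


_AXIS_DIRS = {
    (1, -1): (0.0, 0.0),  # gantry 0: beam along -y
    (1, 1): (180.0, 0.0),
    (0, -1): (90.0, 0.0),  # beam along -x
    (0, 1): (270.0, 0.0),
}


def _build_phantom(spec: CaseSpec, rng: np.random.Generator):
    """Voxelize the target inside a uniform-water box for an axis-aligned beam."""
    g = spec.gantry_deg % 360.0
    if spec.couch_deg % 360.0 != 0.0 or g not in (0.0, 90.0, 180.0, 270.0):
        raise InfeasibleError(
            "the synthetic phantom builder supports axis-aligned beams only "
            "(gantry in {0, 90, 180, 270}, couch 0)"
        )
    axis = 1 if g in (0.0, 180.0) else 0
    sign = -1 if g in (0.0, 90.0) else 1  # beam travels toward sign*axis

    s = spec.spacing_cm
    if spec.shape == "cuboid":
        half = [l / 2.0 for l in spec.size_cm]
    else:
        half = list(spec.size_cm)
    lat_axes = [a for a in range(3) if a != axis]
    margin = 1.5
    n = [0, 0, 0]
    for a in lat_axes:
        n[a] = int(math.ceil(2 * (half[a] + margin) / s))
    depth_extent = spec.distal_depth_cm + 1.0
    n[axis] = int(math.ceil(depth_extent / s))
    shape = tuple(n)
    origin = np.zeros(3)
    density = DensityGrid.uniform_water(origin, (s, s, s), shape)
    upper = density.upper

    # target center: distal-most point at distal_depth below the entry face
    center = np.array([upper[a] / 2.0 for a in range(3)])
    depth_len = half[axis]  # half-extent along the beam axis
    if sign < 0:  # beam enters at the upper face, downstream is decreasing coord
        center[axis] = upper[axis] - spec.distal_depth_cm + depth_len
    else:
        center[axis] = spec.distal_depth_cm - depth_len

    idx = np.indices(shape, dtype=float)
    coords = [origin[a] + (idx[a] + 0.5) * s for a in range(3)]
    rel = [(coords[a] - center[a]) for a in range(3)]
    if spec.shape == "cuboid":
        # snap faces to voxel boundaries via index ranges for exact V and A
        occ = np.ones(shape, dtype=bool)
        for a in range(3):
            i0 = int(round((center[a] - half[a] - origin[a]) / s))
            i1 = int(round((center[a] + half[a] - origin[a]) / s))
            sel = np.zeros(shape[a], dtype=bool)
            sel[max(i0, 0) : min(i1, shape[a])] = True
            occ &= sel.reshape([-1 if b == a else 1 for b in range(3)])
    else:
        rho = np.sqrt(sum((rel[a] / half[a]) ** 2 for a in range(3)))
        if spec.shape == "ellipsoid":
            occ = rho <= 1.0
        else:
            thresh = np.ones(shape)
            for _ in range(4):
                k = rng.normal(size=3)
                k *= rng.uniform(2.0, 4.0) / np.linalg.norm(k)
                phase = rng.uniform(0, 2 * np.pi)
                with np.errstate(invalid="ignore", divide="ignore"):
                    nx = [np.where(rho > 0, rel[a] / half[a] / np.maximum(rho, 1e-9), 0.0) for a in range(3)]
                arg = sum(k[a] * nx[a] for a in range(3)) + phase
                thresh += (spec.blob_amplitude / 2.0) * np.cos(arg)
            occ = rho <= thresh
    if not occ.any():
        raise GeometryError("generated target is empty; spec too small for the grid")
    lo_t, hi_t = np.argwhere(occ).min(axis=0), np.argwhere(occ).max(axis=0)
    if np.any(lo_t <= 0) or np.any(hi_t >= np.array(shape) - 1):
        raise InfeasibleError("target touches the phantom boundary; spec infeasible")
    mask = VoxelMask(origin, (s, s, s), occ)

    gantry, couch = _AXIS_DIRS[(axis, sign)]
    iso = mask.centroid()
    if spec.range_shifted:
        # distance from the isocenter upstream to the (flat) phantom surface
        if sign < 0:
            iso_to_surface = upper[axis] - iso[axis]
        else:
            iso_to_surface = iso[axis] - origin[axis]
        face_distance = iso_to_surface + spec.gap_cm
    else:
        face_distance = 0.0
    beam = BeamGeometry(
        gantry_deg=gantry,
        couch_deg=couch,
        isocenter=iso,
        range_shifted=spec.range_shifted,
        shifter_wet=ToyModelConfig().shifter_wet_cm,
        shifter_face_distance=face_distance,
    )
    return mask, density, beam


def toy_ground_truth(
    mask: VoxelMask,
    density: DensityGrid,
    beam: BeamGeometry,
    prescribed_dose_cgy: float,
    cfg: ToyModelConfig,
    pixel_cm: Optional[float] = None,
) -> float:
    """MU required by the full toy engine to deliver the prescribed dose.

    Every BEV ray gets its own SFUD SOBP kernel spanning that ray's
    water-equivalent chord through the target; layer fluences are blurred with
    the lateral spot kernel and summed at the central-axis SOBP midpoint,
    where the prescription is defined.
    """
    if prescribed_dose_cgy <= 0:
        raise ValidationError("prescribed dose must be > 0")
    d = beam.direction
    pixel = float(min(mask.spacing)) if pixel_cm is None else pixel_cm
    tr = trace_rays(mask, d, pixel, density=density)
    if tr.n_hit == 0:
        raise GeometryError("beam misses the target")

    shifted = beam.range_shifted
    offset = beam.shifter_wet if shifted else 0.0
    gap = air_gap(density, beam) if shifted else 1.0
    dl = cfg.layer_spacing_cm

    dn = tr.wed_exit + offset
    pn = tr.wed_entry + offset
    d_idx = np.round(dn / dl).astype(int)
    p_idx = np.minimum(np.round(pn / dl).astype(int), d_idx)

    mlr = cfg.engine_min_range_cm
    pairs = {}
    for i, key in enumerate(zip(d_idx, p_idx)):
        pairs.setdefault(key, []).append(i)

    kernels = {}
    all_ids = set()
    for (di, pi) in pairs:
        distal = di * dl
        width = max((di - pi) * dl, dl)
        plan = _solve_kernel(cfg, distal, width, mlr)
        ids = np.round(plan.ranges / dl).astype(int)
        kernels[(di, pi)] = (ids, plan.weights)
        all_ids.update(ids.tolist())

    layer_ids = np.array(sorted(all_ids))
    id_pos = {lid: k for k, lid in enumerate(layer_ids)}
    n_layers = layer_ids.size
    n_hit = tr.n_hit
    phi = np.zeros((n_layers, n_hit))
    for key, rays in pairs.items():
        ids, w = kernels[key]
        rows = np.array([id_pos[x] for x in ids])
        phi[np.ix_(rows, np.array(rays))] += w[:, None]

    # BEV coordinates of the hit pixels and the evaluation ray
    uu, vv = np.meshgrid(tr.pixel_u, tr.pixel_v, indexing="ij")
    u_hit = uu.reshape(-1)[tr.hit]
    v_hit = vv.reshape(-1)[tr.hit]
    c = mask.centroid()
    u_c, v_c = float(c @ tr.u), float(c @ tr.v)
    j = int(np.argmin((u_hit - u_c) ** 2 + (v_hit - v_c) ** 2))
    z_eval = 0.5 * (tr.wed_entry[j] + tr.wed_exit[j]) + offset
    u_e, v_e = u_hit[j], v_hit[j]

    dose = 0.0
    for k, lid in enumerate(layer_ids):
        r = lid * dl
        w_row = phi[k]
        if not np.any(w_row):
            continue
        sig = lateral_sigma(cfg, r, shifted, gap)
        g = np.exp(-((u_hit - u_e) ** 2 + (v_hit - v_e) ** 2) / (2.0 * sig**2))
        lat = float(w_row @ g) * pixel**2 / (2.0 * math.pi * sig**2)
        dose += float(_bragg_dose(z_eval, r, cfg)) * lat
    if dose <= 0:
        raise GeometryError("toy engine produced zero dose at the evaluation point")
    mu_per_unit = float(phi.sum()) * pixel**2 / cfg.spot_spacing_cm**2
    return prescribed_dose_cgy * mu_per_unit / dose


def generate_case(
    case_spec: CaseSpec,
    config: ToyModelConfig = ToyModelConfig(),
    seed: int = 0,
) -> SyntheticCase:
    """Materialize a synthetic case and its toy-engine ground-truth MU.

    Deterministic for fixed (spec, config, seed); the random-blob surface is
    the only stochastic element.
    """
    tag = zlib.crc32(case_spec.beam_id.encode())  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag]))
    mask, density, beam = _build_phantom(case_spec, rng)
    mu = toy_ground_truth(mask, density, beam, case_spec.prescribed_dose_cgy, config)
    return SyntheticCase(
        mask=mask,
        density=density,
        beam=beam,
        prescribed_dose_cgy=case_spec.prescribed_dose_cgy,
        mu_ground_truth=mu,
        site_label=case_spec.site_label,
        beam_id=case_spec.beam_id or "beam",
        spec=case_spec,
    )


def node_case_specs(config: ToyModelConfig = ToyModelConfig()) -> list:
    """42 cuboid cases sitting exactly on factor-table nodes.

    Three families mirror the three table-building experiments: OF nodes at
    the reference depth, the translated cube at DF nodes, and the shifted cube
    over AGF gap nodes.
    """
    specs = []
    of_nodes = [
        (3, 2), (3, 5), (3, 10), (4, 2), (4, 4), (4, 8), (5, 2), (5, 4), (5, 5),
        (5, 10), (6, 2), (6, 4), (6, 8), (6, 10), (8, 2), (8, 5), (8, 8), (8, 10),
        (10, 2), (10, 4), (10, 8), (10, 10),
    ]
    for side, width in of_nodes:
        specs.append(
            CaseSpec(
                shape="cuboid",
                size_cm=(float(side), float(width), float(side)),
                distal_depth_cm=20.0,
                site_label="node_of",
                beam_id=f"of_a{side * side}_w{width}",
            )
        )
    for r in (10, 12, 14, 16, 18, 22, 24, 26, 28, 30):
        specs.append(
            CaseSpec(
                shape="cuboid",
                size_cm=(5.0, 5.0, 5.0),
                distal_depth_cm=float(r),
                site_label="node_df",
                beam_id=f"df_r{r}",
            )
        )
    for g in range(1, 11):
        specs.append(
            CaseSpec(
                shape="cuboid",
                size_cm=(5.0, 5.0, 5.0),
                distal_depth_cm=AGF_CUBE_DISTAL_CM,
                range_shifted=True,
                gap_cm=float(g),
                site_label="node_agf",
                beam_id=f"agf_g{g}",
            )
        )
    return specs


_SITE_RECIPES = {
    "pelvis": dict(shapes=("ellipsoid",), lat=(2.5, 4.0), depth_half=(1.2, 2.6),
                   distal=(16.0, 24.0), shifted=False),
    "brain": dict(shapes=("blob", "ellipsoid"), lat=(1.5, 2.8), depth_half=(1.0, 2.2),
                  distal=(8.0, 14.0), shifted=False),
    "lung": dict(shapes=("ellipsoid", "blob"), lat=(1.5, 3.2), depth_half=(1.0, 2.4),
                 distal=(10.0, 18.0), shifted=False),
    "head_neck": dict(shapes=("blob",), lat=(1.8, 3.0), depth_half=(0.9, 1.6),
                      distal=(4.5, 7.0), shifted=True, gaps=(1.0, 6.0)),
}


def shaped_case_specs(
    n: int, seed: int, config: ToyModelConfig = ToyModelConfig()
) -> list:
    """Seeded non-cuboid (ellipsoid/blob) specs across the four site labels."""
    rng = np.random.default_rng(seed)
    sites = list(_SITE_RECIPES)
    specs = []
    gantries = (0.0, 90.0, 180.0)
    for i in range(n):
        site = sites[i % len(sites)]
        r = _SITE_RECIPES[site]
        shape = r["shapes"][int(rng.integers(len(r["shapes"])))]
        distal = float(rng.uniform(*r["distal"]))
        max_half = min(r["depth_half"][1], (distal - 1.5) / 2.0)
        dh = float(rng.uniform(r["depth_half"][0], max(max_half, r["depth_half"][0] + 0.05)))
        lat1 = float(rng.uniform(*r["lat"]))
        lat2 = float(rng.uniform(*r["lat"]))
        gap = float(rng.uniform(*r["gaps"])) if r["shifted"] else 1.0
        specs.append(
            CaseSpec(
                shape=shape,
                size_cm=(lat1, dh, lat2),
                distal_depth_cm=distal,
                gantry_deg=gantries[int(rng.integers(len(gantries)))] if site != "head_neck" else 0.0,
                range_shifted=r["shifted"],
                gap_cm=gap,
                site_label=site,
                beam_id=f"{site}_{i:03d}",
            )
        )
    return specs


def generate_bundle(
    specs: Sequence[CaseSpec],
    config: ToyModelConfig = ToyModelConfig(),
    seed: int = 0,
) -> list:
    return [generate_case(s, config, seed) for s in specs]
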