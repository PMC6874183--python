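"""Secondary MU calculation from the equivalent-cuboid model.

The target is summarized as a cuboid with the target's volume and BEV
projected area; its SOBP width is volume/area and its effective range is the
mean distal-surface WED (plus the shifter WET for range-shifted beams).  The
monitor units for a beam are then

    MU = prescribed_dose / (OF(area, width) * DF(range) * AGF(gap) * calibration)

and the result is compared against the TPS-prescribed MU as
``100 * (calc - tps) / tps``.  Only SFUD-optimized beams are in scope;
multifield-optimized beams are refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ScopeError, ValidationError
from .factors import FactorSet, air_gap_factor, depth_factor, output_factor
from .geometry import (
    BeamGeometry,
    DensityGrid,
    VoxelMask,
    air_gap,
    bev_projected_area,
    distal_surface_wed,
    mask_volume,
)

__all__ = [
    "CuboidModel",
    "BeamMUResult",
    "cuboid_from_measurements",
    "compute_mu",
    "compare_mu",
    "summarize",
    "percent_diff_histogram",
    "measure_case",
    "check_case",
]


@dataclass(frozen=True)
class CuboidModel:
    """Equivalent-cuboid summary of one (target, beam) pair."""

    volume_cm3: float
    bev_area_cm2: float
    sobp_width_cm: float
    distal_wed_cm: float
    effective_range_cm: float
    air_gap_cm: Optional[float] = None  # None for open fields

    def __post_init__(self):
        for name in ("volume_cm3", "bev_area_cm2", "sobp_width_cm", "distal_wed_cm", "effective_range_cm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(self.sobp_width_cm * self.bev_area_cm2 - self.volume_cm3) > 1e-9 * self.volume_cm3:
            raise ValidationError("width * area must equal volume")
        if self.effective_range_cm < self.distal_wed_cm - 1e-12:
            raise ValidationError("effective range cannot be shallower than the distal WED")


def cuboid_from_measurements(
    volume_cm3: float,
    bev_area_cm2: float,
    distal_wed_cm: float,
    beam: BeamGeometry,
    gap_cm: Optional[float] = None,
) -> CuboidModel:
    """Collapse the geometric measurements into the model cuboid.

    SOBP width is volume/area; for range-shifted beams the shifter WET is
    added to the measured distal WED to form the effective beam range.
    """
    if volume_cm3 <= 0 or bev_area_cm2 <= 0 or distal_wed_cm <= 0:
        raise ValidationError("volume, area and distal WED must all be > 0")
    width = volume_cm3 / bev_area_cm2
    eff = distal_wed_cm + (beam.shifter_wet if beam.range_shifted else 0.0)
    if width > eff:
        raise ValidationError(
            f"SOBP width {width:.2f} cm exceeds the effective range {eff:.2f} cm; "
            "the cuboid approximation breaks down for this geometry"
        )
    return CuboidModel(
        volume_cm3=volume_cm3,
        bev_area_cm2=bev_area_cm2,
        sobp_width_cm=width,
        distal_wed_cm=distal_wed_cm,
        effective_range_cm=eff,
        air_gap_cm=gap_cm if beam.range_shifted else None,
    )


@dataclass
class BeamMUResult:
    """Computed MU with its factor decomposition and optional TPS comparison."""

    mu_calculated: float
    components: dict
    cuboid: Optional[CuboidModel] = None
    mu_tps: Optional[float] = None
    percent_diff: Optional[float] = None
    warnings: list = field(default_factory=list)
    beam_id: str = ""
    site_label: str = ""


def compute_mu(
    prescribed_dose_cgy: float,
    cuboid: CuboidModel,
    fset: FactorSet,
    range_shifted: bool,
) -> BeamMUResult:
    """MU = dose / (OF * DF * AGF * calibration), with clamp warnings propagated."""
    if prescribed_dose_cgy <= 0:
        raise ValidationError("prescribed dose must be > 0")
    of = output_factor(fset, cuboid.bev_area_cm2, cuboid.sobp_width_cm, range_shifted)
    df = depth_factor(fset, cuboid.effective_range_cm)
    gap = cuboid.air_gap_cm if cuboid.air_gap_cm is not None else fset.reference.gap_cm
    agf = air_gap_factor(fset, gap, range_shifted)
    components = {
        "of": of.value,
        "df": df.value,
        "agf": agf.value,
        "calibration": fset.calibration,
    }
    for name, val in components.items():
        if val <= 0:
            raise ValidationError(f"factor {name} is non-positive: corrupt tables")
    mu = prescribed_dose_cgy / (of.value * df.value * agf.value * fset.calibration)
    return BeamMUResult(
        mu_calculated=mu,
        components=components,
        cuboid=cuboid,
        warnings=list(of.warnings + df.warnings + agf.warnings),
    )


def compare_mu(result: BeamMUResult, mu_tps: float) -> BeamMUResult:
    """Attach the TPS MU and the signed percent difference (calc - tps)/tps."""
    if mu_tps <= 0:
        raise ValidationError("TPS MU must be > 0")
    result.mu_tps = float(mu_tps)
    result.percent_diff = 100.0 * (result.mu_calculated - mu_tps) / mu_tps
    return result


def summarize(results: Sequence[BeamMUResult]) -> pd.DataFrame:
    """Per-site mean/SD of percent differences plus a pooled 'total' row.

    Sample (n-1) standard deviation; for a single-beam group the SD is
    reported as 0 with ``sd_defined`` False.
    """
    rows = [(r.site_label or "all", r.percent_diff) for r in results if r.percent_diff is not None]
    if not rows:
        raise ValidationError("no results with percent differences to summarize")
    df = pd.DataFrame(rows, columns=["site", "pct"])

    def _stats(group: pd.Series) -> tuple:
        n = len(group)
        sd = float(group.std(ddof=1)) if n > 1 else 0.0
        return n, float(group.mean()), sd, n > 1

    out = []
    for site, group in df.groupby("site", sort=True):
        n, mean, sd, ok = _stats(group["pct"])
        out.append({"site": site, "n_beams": n, "mean_pct": mean, "sd_pct": sd, "sd_defined": ok})
    n, mean, sd, ok = _stats(df["pct"])
    out.append({"site": "total", "n_beams": n, "mean_pct": mean, "sd_pct": sd, "sd_defined": ok})
    return pd.DataFrame(out)


def percent_diff_histogram(
    results: Sequence[BeamMUResult], bin_width_pct: float = 1.0
) -> dict:
    """Histogram of all percent differences (for the JSON report)."""
    vals = np.array([r.percent_diff for r in results if r.percent_diff is not None])
    if vals.size == 0:
        raise ValidationError("no percent differences to histogram")
    lo = np.floor(vals.min() / bin_width_pct) * bin_width_pct
    hi = np.ceil(vals.max() / bin_width_pct) * bin_width_pct + bin_width_pct
    edges = np.arange(lo, hi + 1e-9, bin_width_pct)
    counts, edges = np.histogram(vals, bins=edges)
    return {"bin_edges_pct": edges.tolist(), "counts": counts.tolist()}


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def measure_case(
    mask: VoxelMask,
    density: DensityGrid,
    beam: BeamGeometry,
    pixel_cm: Optional[float] = None,
    surface_threshold: float = 0.2,
) -> CuboidModel:
    """Run all geometric measurements and collapse them into the cuboid."""
    pixel = float(min(mask.spacing)) if pixel_cm is None else pixel_cm
    d = beam.direction
    vol = mask_volume(mask)
    area = bev_projected_area(mask, d, pixel)
    wed = distal_surface_wed(mask, density, d, pixel, surface_threshold).mean_cm
    gap = air_gap(density, beam, mask, surface_threshold) if beam.range_shifted else None
    return cuboid_from_measurements(vol, area, wed, beam, gap)


def check_case(
    case,
    fset: FactorSet,
    pixel_cm: Optional[float] = None,
    surface_threshold: float = 0.2,
) -> BeamMUResult:
    """Measure, compute and (when a TPS MU is present) compare one case.

    ``case`` is anything with mask/density/beam/prescribed_dose_cgy plus
    optional mu_tps or mu_ground_truth, beam_id, site_label and technique
    attributes (a :class:`~mucheck.beam_model.SyntheticCase` or a loaded case
    file).
    """
    technique = getattr(case, "technique", "sfud")
    if technique not in ("sfud", "SFUD"):
        raise ScopeError(
            f"beam technique {technique!r} is outside this method's scope: "
            "results will be poor for multifield-optimized beams"
        )
    cuboid = measure_case(case.mask, case.density, case.beam, pixel_cm, surface_threshold)
    result = compute_mu(case.prescribed_dose_cgy, cuboid, fset, case.beam.range_shifted)
    result.beam_id = getattr(case, "beam_id", "")
    result.site_label = getattr(case, "site_label", "")
    mu_tps = getattr(case, "mu_tps", None)
    if mu_tps is None:
        mu_tps = getattr(case, "mu_ground_truth", None)
    if mu_tps is not None:
        compare_mu(result, mu_tps)
    return result
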