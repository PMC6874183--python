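"""Empirical factor tables: output factor (OF), depth factor (DF), air-gap
factor (AGF), their reference conditions, and interpolation.

The OF is a 2-D table in (BEV area, SOBP width) in cGy/MU, tabulated at a
reference depth in water of 20 cm and (for range-shifted delivery) a reference
air gap of 1 cm.  DF and AGF are dimensionless ratios normalized to 1 at the
reference depth (20 cm) and reference gap (1 cm) respectively.

Interpolation policy: bilinear for the OF grid; monotone piecewise cubic
(PCHIP, overshoot-free) for the 1-D tables with a linear fallback.  Queries
outside a table clamp to the boundary and raise a machine-readable warning
flag — a second-check tool fails safe rather than extrapolating.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .errors import ValidationError

__all__ = [
    "FactorTable1D",
    "FactorTable2D",
    "ReferenceConditions",
    "FactorSet",
    "FactorValue",
    "output_factor",
    "depth_factor",
    "air_gap_factor",
    "load_factor_set",
    "save_factor_set",
]

RENORM_TOLERANCE = 0.02

CLAMP_OF = "of_query_clamped"
CLAMP_DF = "df_query_clamped"
CLAMP_AGF = "agf_query_clamped"


class FactorValue(NamedTuple):
    """An interpolated factor plus any clamp warnings raised by the query."""

    value: float
    warnings: tuple = ()


def _check_axis(axis: np.ndarray, name: str) -> np.ndarray:
    axis = np.asarray(axis, dtype=float).reshape(-1)
    if axis.size < 2:
        raise ValidationError(f"{name} needs at least two samples")
    if np.any(np.diff(axis) <= 0):
        raise ValidationError(f"{name} must be strictly ascending")
    return axis


@dataclass(frozen=True)
class FactorTable2D:
    """Output-factor grid: values[i, j] at (area_axis[i], width_axis[j])."""

    area_axis: np.ndarray
    width_axis: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "area_axis", _check_axis(self.area_axis, "area axis"))
        object.__setattr__(self, "width_axis", _check_axis(self.width_axis, "width axis"))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.area_axis.size, self.width_axis.size):
            raise ValidationError(
                f"OF table shape {vals.shape} inconsistent with axes "
                f"({self.area_axis.size}, {self.width_axis.size})"
            )
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("OF values must be finite and > 0")
        object.__setattr__(self, "values", vals)

    def interp(self, area: float, width: float) -> FactorValue:
        warnings = []
        a = float(np.clip(area, self.area_axis[0], self.area_axis[-1]))
        w = float(np.clip(width, self.width_axis[0], self.width_axis[-1]))
        if a != area or w != width:
            warnings.append(CLAMP_OF)
        f = RegularGridInterpolator(
            (self.area_axis, self.width_axis), self.values, method="linear"
        )
        return FactorValue(float(f((a, w))), tuple(warnings))


@dataclass(frozen=True)
class FactorTable1D:
    """1-D factor curve (DF vs range, AGF vs gap)."""

    axis: np.ndarray
    values: np.ndarray
    method: str = "pchip"  # or "linear"

    def __post_init__(self):
        object.__setattr__(self, "axis", _check_axis(self.axis, "axis"))
        vals = np.asarray(self.values, dtype=float).reshape(-1)
        if vals.size != self.axis.size:
            raise ValidationError("1-D table axis/value length mismatch")
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("factor values must be finite and > 0")
        object.__setattr__(self, "values", vals)
        if self.method not in ("pchip", "linear"):
            raise ValidationError(f"unknown interpolation method {self.method!r}")

    def _interpolant(self):
        if self.method == "pchip":
            return PchipInterpolator(self.axis, self.values, extrapolate=False)
        return lambda x: np.interp(x, self.axis, self.values)

    def interp(self, x: float, clamp_warning: str) -> FactorValue:
        warnings = []
        xc = float(np.clip(x, self.axis[0], self.axis[-1]))
        if xc != x:
            warnings.append(clamp_warning)
        return FactorValue(float(self._interpolant()(xc)), tuple(warnings))

    def value_at(self, x: float) -> float:
        if not (self.axis[0] - 1e-9 <= x <= self.axis[-1] + 1e-9):
            raise ValidationError(f"reference abscissa {x} outside table domain")
        xc = float(np.clip(x, self.axis[0], self.axis[-1]))
        return float(self._interpolant()(xc))

    def normalized_at(self, x: float, tolerance: float = RENORM_TOLERANCE):
        """Renormalize so the curve equals 1 at ``x``; reject if off by > tolerance."""
        ref = self.value_at(x)
        if abs(ref - 1.0) > tolerance:
            raise ValidationError(
                f"table value at reference abscissa {x} is {ref:.4f}; "
                f"more than {tolerance:.0%} from 1 — inconsistent data"
            )
        return replace(self, values=self.values / ref)


@dataclass(frozen=True)
class ReferenceConditions:
    depth_cm: float = 20.0
    gap_cm: float = 1.0
    shifter_wet_cm: float = 4.1


@dataclass(frozen=True)
class FactorSet:
    """The three lookup tables plus reference conditions and calibration."""

    of_open: FactorTable2D
    of_shifted: FactorTable2D
    df: FactorTable1D
    agf: FactorTable1D
    reference: ReferenceConditions = field(default_factory=ReferenceConditions)
    calibration: float = 1.0  # measured cGy/MU scale from patient QA

    def __post_init__(self):
        if self.calibration <= 0:
            raise ValidationError("calibration must be > 0")
        for tbl, x, what in (
            (self.df, self.reference.depth_cm, "DF at reference depth"),
            (self.agf, self.reference.gap_cm, "AGF at reference gap"),
        ):
            if abs(tbl.value_at(x) - 1.0) > 1e-6:
                raise ValidationError(f"{what} must equal 1 within 1e-6 (normalize first)")


def output_factor(
    fset: FactorSet, area_cm2: float, sobp_width_cm: float, range_shifted: bool
) -> FactorValue:
    """Bilinear OF lookup in cGy/MU; out-of-grid queries clamp with a warning."""
    if area_cm2 <= 0 or sobp_width_cm <= 0:
        raise ValidationError("area and SOBP width must be > 0")
    table = fset.of_shifted if range_shifted else fset.of_open
    return table.interp(area_cm2, sobp_width_cm)


def depth_factor(fset: FactorSet, range_cm: float) -> FactorValue:
    """DF at the given (effective) beam range; DF(reference depth) = 1."""
    if range_cm <= 0:
        raise ValidationError("range must be > 0")
    return fset.df.interp(range_cm, CLAMP_DF)


def air_gap_factor(fset: FactorSet, gap_cm: float, range_shifted: bool) -> FactorValue:
    """AGF for range-shifted delivery; open fields return exactly 1."""
    if gap_cm < 0:
        raise ValidationError("air gap must be >= 0")
    if not range_shifted:
        return FactorValue(1.0, ())
    return fset.agf.interp(gap_cm, CLAMP_AGF)


# ---------------------------------------------------------------------------
# CSV / sidecar I/O
# ---------------------------------------------------------------------------
#
# OF CSV:   header "sobp_width_cm,<area values...>" then one row per width.
# DF CSV:   "range_cm,factor"
# AGF CSV:  "gap_cm,factor"
# Sidecar (YAML): reference conditions, calibration, file names.


def _read_csv_matrix(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[0] != "sobp_width_cm":
        raise ValidationError(f"{path}: OF CSV header must start with 'sobp_width_cm'")
    area_axis = np.array([float(x) for x in header[1:]])
    body = np.atleast_2d(np.genfromtxt(path, delimiter=",", skip_header=1))
    widths = body[:, 0]
    values = body[:, 1:]  # (n_width, n_area)
    order_w = np.argsort(widths)
    order_a = np.argsort(area_axis)
    return area_axis[order_a], widths[order_w], values[np.ix_(order_w, order_a)].T


def read_of_csv(path: str) -> FactorTable2D:
    area, width, values = _read_csv_matrix(path)
    return FactorTable2D(area_axis=area, width_axis=width, values=values)


def read_1d_csv(path: str, x_name: str, method: str = "pchip") -> FactorTable1D:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header != [x_name, "factor"]:
        raise ValidationError(f"{path}: expected header '{x_name},factor', got {header}")
    body = np.atleast_2d(np.genfromtxt(path, delimiter=",", skip_header=1))
    order = np.argsort(body[:, 0])
    return FactorTable1D(axis=body[order, 0], values=body[order, 1], method=method)


def write_of_csv(table: FactorTable2D, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sobp_width_cm," + ",".join(repr(float(a)) for a in table.area_axis) + "\n")
        for j, w in enumerate(table.width_axis):
            fh.write(repr(float(w)) + "," + ",".join(repr(float(v)) for v in table.values[:, j]) + "\n")


def write_1d_csv(table: FactorTable1D, path: str, x_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{x_name},factor\n")
        for x, v in zip(table.axis, table.values):
            fh.write(f"{float(x)!r},{float(v)!r}\n")


SIDE_CAR = "factors.yaml"


def save_factor_set(fset: FactorSet, directory: str) -> None:
    import yaml

    os.makedirs(directory, exist_ok=True)
    write_of_csv(fset.of_open, os.path.join(directory, "of_open.csv"))
    write_of_csv(fset.of_shifted, os.path.join(directory, "of_shifted.csv"))
    write_1d_csv(fset.df, os.path.join(directory, "df.csv"), "range_cm")
    write_1d_csv(fset.agf, os.path.join(directory, "agf.csv"), "gap_cm")
    meta = {
        "reference": {
            "depth_cm": float(fset.reference.depth_cm),
            "gap_cm": float(fset.reference.gap_cm),
            "shifter_wet_cm": float(fset.reference.shifter_wet_cm),
        },
        "calibration_cgy_per_mu": float(fset.calibration),
        "interpolation_1d": fset.df.method,
        "files": {
            "of_open": "of_open.csv",
            "of_shifted": "of_shifted.csv",
            "df": "df.csv",
            "agf": "agf.csv",
        },
    }
    with open(os.path.join(directory, SIDE_CAR), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_factor_set(
    directory: str, reference_config: Optional[dict] = None
) -> FactorSet:
    """Load and validate a factor set from a directory with a YAML sidecar.

    DF/AGF are renormalized at their reference abscissae if within 2% of 1 and
    rejected otherwise.
    """
    import yaml

    sidecar = os.path.join(directory, SIDE_CAR)
    if not os.path.exists(sidecar):
        raise ValidationError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    ref_meta = dict(meta.get("reference", {}))
    if reference_config:
        ref_meta.update(reference_config)
    reference = ReferenceConditions(
        depth_cm=float(ref_meta.get("depth_cm", 20.0)),
        gap_cm=float(ref_meta.get("gap_cm", 1.0)),
        shifter_wet_cm=float(ref_meta.get("shifter_wet_cm", 4.1)),
    )
    files = meta.get("files", {})
    method = meta.get("interpolation_1d", "pchip")

    def _p(key, default):
        return os.path.join(directory, files.get(key, default))

    of_open = read_of_csv(_p("of_open", "of_open.csv"))
    of_shifted_path = _p("of_shifted", "of_shifted.csv")
    of_shifted = read_of_csv(of_shifted_path) if os.path.exists(of_shifted_path) else of_open
    df = read_1d_csv(_p("df", "df.csv"), "range_cm", method).normalized_at(reference.depth_cm)
    agf = read_1d_csv(_p("agf", "agf.csv"), "gap_cm", method).normalized_at(reference.gap_cm)
    return FactorSet(
        of_open=of_open,
        of_shifted=of_shifted,
        df=df,
        agf=agf,
        reference=reference,
        calibration=float(meta.get("calibration_cgy_per_mu", 1.0)),
    )
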