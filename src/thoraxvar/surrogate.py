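"""Deterministic surrogate of the thorax crash response.

Finite-element occupant crash simulation is far outside desk scale, so this
module provides a documented, deterministic stand-in that maps a 15-coordinate
:class:`~thoraxvar.parametric_model.ParameterVector` and a load case to
per-rib peak cortical strains.  It is explicitly NOT a fidelity claim about
any particular human body model: it preserves the one piece of physics that
drives rib strain under bending -- the flexural rigidity E*I of an
elliptical-annulus rib cross-section -- plus weak, configurable modulation
from the remaining parameters:

    eps_r = M_r * c_r / (E * I_r) * A_soft * A_cart

where ``M_r`` is the rib's share of a calibrated bending-moment budget
(redistributed slightly by the ribcage shape modes), ``c_r`` the extreme
fiber distance along the bending direction, ``E`` the cortical Young's
modulus, ``I_r`` the area moment of the cortical annulus about the bending
axis, and ``A_soft``/``A_cart`` mild attenuation factors for the soft-tissue
and cartilage/trabecular coordinates.  Both impact directions bend the ribs
about the cross-section's major (height) axis, so the rib *width* is the
dominating cubed dimension -- in a frontal impact the tensile fiber is on
the cutaneous side of the rib, in a near-side impact on the pleural side of
the struck-side ribs; for the symmetric annulus the two fibers are
equidistant, so the convention is recorded per load case but does not change
the strain magnitude.

The load magnitude is calibrated, per load case, so that the cut-point model
(all s = 0) predicts a stated NFR2+ risk; every downstream statistic is then
relative to that anchor.  All surrogate constants are config data with
documented defaults chosen so the surrogate reproduces the qualitative
importance ranking expected from beam physics (thickness and material and
width dominate); they are modelling choices, not discovered results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .parametric_model import (
    GeometryConvention,
    PER_SD_CONVENTION,
    ParameterVector,
    scale_cortical,
    scale_geometry,
)
from .risk_model import (
    DEFAULT_AGE_YEARS,
    DEFAULT_RISK_FUNCTION,
    RiskFunction,
    nfr2plus,
    rib_fracture_probability,
)

__all__ = [
    "RibSection",
    "LoadCase",
    "StrainResult",
    "RIB_INDEX",
    "elliptical_annulus",
    "bending_strain",
    "default_load_case",
    "peak_rib_strain",
    "calibrate_load",
    "conserve_mass",
    "CalibrationError",
    "TabulatedStrainModel",
    "write_strain_csv",
    "save_load_case",
    "load_load_case",
]


class CalibrationError(RuntimeError):
    """Raised when a load case cannot be calibrated to the target risk."""


#: canonical rib order: left levels 1..12 then right levels 1..12
RIB_INDEX: Tuple[Tuple[str, int], ...] = tuple(
    (side, level) for side in ("left", "right") for level in range(1, 13)
)


@dataclass(frozen=True)
class RibSection:
    """Elliptical-annulus rib cross-section (mm / mm^2 / mm^4).

    ``W`` is the outer minor-axis (width) diameter, ``H`` the outer
    major-axis (height) diameter, ``t`` the cortical thickness.
    ``I_about_height_axis`` resists bending that flexes the rib in the width
    direction (width is the cubed dimension); ``I_about_width_axis`` the
    orthogonal one.  ``I_max``/``I_min`` are the same two values ordered by
    magnitude.
    """

    W: float
    H: float
    t: float
    area: float
    I_about_width_axis: float
    I_about_height_axis: float

    @property
    def I_max(self) -> float:
        return max(self.I_about_width_axis, self.I_about_height_axis)

    @property
    def I_min(self) -> float:
        return min(self.I_about_width_axis, self.I_about_height_axis)


def elliptical_annulus(W: float, H: float, t: float) -> RibSection:
    """Closed-form area and second moments of an elliptical annulus.

    Outer semi-axes (W/2, H/2); inner semi-axes reduced by the cortical
    thickness t on all sides.  Requires 2t < min(W, H).
    """
    if min(W, H, t) <= 0:
        raise ValueError("W, H, t must be positive")
    if 2.0 * t >= min(W, H):
        raise ValueError(f"degenerate section: 2t={2 * t} >= min(W, H)={min(W, H)}")
    a, b = W / 2.0, H / 2.0
    ai, bi = a - t, b - t
    area = math.pi * (a * b - ai * bi)
    # I about the width axis: height is the cubed dimension
    i_w = math.pi / 4.0 * (a * b**3 - ai * bi**3)
    # I about the height axis: width is the cubed dimension
    i_h = math.pi / 4.0 * (b * a**3 - bi * ai**3)
    return RibSection(W=W, H=H, t=t, area=area, I_about_width_axis=i_w, I_about_height_axis=i_h)


def bending_strain(moment: float, c: float, E_mpa: float, inertia: float) -> float:
    """Extreme-fiber bending strain eps = M c / (E I).

    Units: moment N*mm, c mm, E MPa (N/mm^2), I mm^4; strain is unitless.
    """
    return moment * c / (E_mpa * inertia)


# ---------------------------------------------------------------------------
# load cases
# ---------------------------------------------------------------------------

# nominal cross-section of a mid-level rib (mm); per-level sizes scale these
NOMINAL_WIDTH_MM = 15.2
NOMINAL_HEIGHT_MM = 16.8
NOMINAL_THICKNESS_MM = 1.0


def _level_scale(level: int) -> float:
    """Gentle growth of rib cross-section from level 1 to 12."""
    return 0.88 + 0.02 * level


# relative load borne by each rib level (before normalisation)
_FRONTAL_LEVEL_WEIGHTS = {2: 0.5, 3: 0.8, 4: 1.0, 5: 1.0, 6: 1.0, 7: 0.8, 8: 0.5}
_NEAR_SIDE_LEVEL_WEIGHTS = {3: 0.4, 4: 0.7, 5: 1.0, 6: 1.0, 7: 1.0, 8: 0.7, 9: 0.4}

#: per-mode strength of the shape-driven load redistribution (mode 1..6)
DEFAULT_SHAPE_MODE_WEIGHTS = (0.030, 0.025, 0.020, 0.015, 0.010, 0.008)

#: log-strain slope per unit s for the weak modulation coordinates
DEFAULT_SOFT_COEFFS = {
    "adipose": 0.005,
    "skeletal_muscle": 0.005,
    "intercostal_muscle": 0.007,
    "cartilage": 0.010,
    "trab_material": 0.006,
}


@dataclass(frozen=True)
class LoadCase:
    """A calibrated impact scenario for the surrogate.

    ``load_share`` distributes the bending-moment budget over the 24 ribs
    (canonical order, non-negative, sums to 1); ``load_magnitude`` is the
    total bending-moment scale in N*mm, set by :func:`calibrate_load` and
    ``None`` until then.  ``fiber_side`` records the tensile-fiber
    convention.  ``shape_mode_weights`` and ``soft_coeffs`` are the weak
    modulation constants documented in the module docstring.
    """

    name: str
    delta_v_kmh: float
    load_share: Tuple[float, ...]
    load_magnitude: Optional[float] = None
    fiber_side: str = "cutaneous"
    shape_mode_weights: Tuple[float, ...] = DEFAULT_SHAPE_MODE_WEIGHTS
    soft_coeffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SOFT_COEFFS))
    geometry_convention: GeometryConvention = PER_SD_CONVENTION

    def __post_init__(self) -> None:
        share = np.asarray(self.load_share, dtype=float)
        if share.size != 24:
            raise ValueError("load_share needs 24 entries")
        if np.any(share < 0):
            raise ValueError("load_share entries must be >= 0")
        if not math.isclose(float(share.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("load_share must sum to 1")
        if self.delta_v_kmh <= 0:
            raise ValueError("delta_v must be positive")
        object.__setattr__(self, "load_share", tuple(float(x) for x in share))

    @property
    def calibrated(self) -> bool:
        return self.load_magnitude is not None


def _normalised_share(level_weights: Mapping[int, float], sides: Sequence[str]) -> Tuple[float, ...]:
    share = np.zeros(24)
    for i, (side, level) in enumerate(RIB_INDEX):
        if side in sides:
            share[i] = level_weights.get(level, 0.0)
    return tuple(share / share.sum())


def default_load_case(name: str) -> LoadCase:
    """Uncalibrated default load cases.

    ``frontal``: 45 km/h delta-v, belt/airbag loading shared bilaterally over
    ribs 2-8 and peaking at ribs 4-6; tensile fiber on the cutaneous side.
    ``near_side``: 24 km/h lateral delta-v, door/airbag loading on the
    struck (left) side over ribs 3-9 peaking laterally; tensile fiber on
    the pleural side.
    """
    if name == "frontal":
        return LoadCase(
            name="frontal",
            delta_v_kmh=45.0,
            load_share=_normalised_share(_FRONTAL_LEVEL_WEIGHTS, ("left", "right")),
            fiber_side="cutaneous",
        )
    if name == "near_side":
        return LoadCase(
            name="near_side",
            delta_v_kmh=24.0,
            load_share=_normalised_share(_NEAR_SIDE_LEVEL_WEIGHTS, ("left",)),
            fiber_side="pleural",
        )
    raise ValueError(f"unknown load case {name!r}")


@dataclass(frozen=True)
class StrainResult:
    """Per-rib peak first-principal strain (unitless, canonical rib order)."""

    epsilon: Tuple[float, ...]
    load_case: str

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.size != 24:
            raise ValueError("epsilon needs 24 entries")
        if np.any(eps < 0):
            raise ValueError("strains must be non-negative")
        object.__setattr__(self, "epsilon", tuple(float(x) for x in eps))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.epsilon, dtype=float)


def _shape_factors(params: ParameterVector, case: LoadCase) -> np.ndarray:
    """Per-rib multiplicative load redistribution from the shape modes.

    A smooth level pattern per mode, renormalised below so the total load is
    preserved under shape perturbation.
    """
    factors = np.ones(24)
    for j, w in enumerate(case.shape_mode_weights, start=1):
        s = params.get(f"shape_pc{j}", 0.0)
        if s == 0.0 or w == 0.0:
            continue
        for i, (_side, level) in enumerate(RIB_INDEX):
            pattern = math.cos(math.pi * j * (level - 0.5) / 12.0)
            factors[i] += w * s * pattern
    return np.clip(factors, 0.2, None)


def peak_rib_strain(params: ParameterVector, case: LoadCase) -> StrainResult:
    """Per-rib peak cortical strain for one parameter vector and load case.

    Deterministic; strictly decreasing in s for cortical thickness, rib
    width and cortical material (the flexural-rigidity parameters).
    Requires a calibrated load case.
    """
    if not case.calibrated:
        raise CalibrationError(f"load case {case.name!r} has no calibrated magnitude")
    gs = scale_geometry(
        params.get("cort_thickness"),
        params.get("rib_width"),
        params.get("rib_height"),
        convention=case.geometry_convention,
    )
    E_mpa = scale_cortical(params.get("cort_material")).E_mpa
    log_atten = sum(
        -coef * params.get(name, 0.0) for name, coef in case.soft_coeffs.items()
    )
    atten = math.exp(log_atten)

    share = np.asarray(case.load_share)
    factors = _shape_factors(params, case)
    weighted = share * factors
    weighted = weighted / weighted.sum()  # preserve the total load budget

    eps = np.zeros(24)
    for i, (_side, level) in enumerate(RIB_INDEX):
        if weighted[i] == 0.0:
            continue
        k = _level_scale(level)
        W = NOMINAL_WIDTH_MM * k + gs.dW
        H = NOMINAL_HEIGHT_MM * k + gs.dH
        t = NOMINAL_THICKNESS_MM * k * gs.T_scale
        section = elliptical_annulus(W, H, t)
        moment = case.load_magnitude * weighted[i]
        eps[i] = bending_strain(moment, W / 2.0, E_mpa, section.I_about_height_axis) * atten
    return StrainResult(epsilon=tuple(eps), load_case=case.name)


def calibrate_load(
    case: LoadCase,
    target_risk: float = 0.51,
    age: float = DEFAULT_AGE_YEARS,
    rf: RiskFunction = DEFAULT_RISK_FUNCTION,
    space=None,
    tol: float = 1e-4,
) -> LoadCase:
    """Set the load magnitude so the cut-point model hits the target NFR2+.

    The cut-point strain vector is linear in the magnitude and NFR2+ is
    strictly increasing in it, so bisection (with bracket expansion until a
    sign change) finds the unique root; the calibrated case reproduces the
    target within ``tol``.
    """
    from scipy.optimize import brentq

    if not 0.0 < target_risk < 1.0:
        raise CalibrationError("target risk must lie strictly between 0 and 1")
    if space is None:
        from .parametric_model import default_parameter_space

        space = default_parameter_space()
    cut = ParameterVector.cut_point(space)
    # cut-point strain per unit moment; strains are linear in the magnitude
    unit_eps = peak_rib_strain(cut, replace(case, load_magnitude=1.0)).as_array()
    if not np.any(unit_eps > 0):
        raise CalibrationError("load case applies no load to any rib")

    def risk_gap(magnitude: float) -> float:
        p = rib_fracture_probability(magnitude * unit_eps, age=age, rf=rf)
        return nfr2plus(p) - target_risk

    lo, hi = 1.0, 1e6
    for _ in range(200):
        if risk_gap(lo) <= 0.0:
            break
        lo /= 10.0
    else:  # pragma: no cover - requires pathological risk function
        raise CalibrationError("could not bracket the target risk from below")
    for _ in range(200):
        if risk_gap(hi) >= 0.0:
            break
        hi *= 10.0
    else:  # pragma: no cover
        raise CalibrationError("could not bracket the target risk from above")
    magnitude = float(brentq(risk_gap, lo, hi, xtol=1e-12, rtol=1e-14))
    if abs(risk_gap(magnitude)) > tol:
        raise CalibrationError(
            f"calibration missed target by {abs(risk_gap(magnitude)):.2e}"
        )
    return replace(case, load_magnitude=magnitude)


def conserve_mass(volume_change: float) -> float:
    """Soft-tissue density scale factor restoring the original torso mass.

    For a fractional volume change v the density factor is 1/(1+v), so the
    product of factor and (1+v) is exactly 1.
    """
    if volume_change <= -1.0:
        raise ValueError("volume change must exceed -100%")
    return 1.0 / (1.0 + volume_change)


# ---------------------------------------------------------------------------
# black-box adapter and I/O
# ---------------------------------------------------------------------------


class TabulatedStrainModel:
    """Adapter substituting precomputed (e.g. finite-element) strain tables.

    The CSV holds one row per evaluated parameter vector: the 15 coordinate
    columns followed by ``rib_01``..``rib_24``.  Lookup is exact on the
    rounded coordinates, so the table must contain every vector the design
    will request.
    """

    DECIMALS = 9

    def __init__(self, table: pd.DataFrame, parameter_names: Sequence[str], case_name: str = "tabulated"):
        self.parameter_names = list(parameter_names)
        self.case_name = case_name
        rib_cols = [f"rib_{i:02d}" for i in range(1, 25)]
        self._lookup: Dict[Tuple[float, ...], np.ndarray] = {}
        for _, row in table.iterrows():
            key = tuple(round(float(row[name]), self.DECIMALS) for name in self.parameter_names)
            self._lookup[key] = row[rib_cols].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, parameter_names: Sequence[str], case_name: str = "tabulated"):
        return cls(pd.read_csv(path), parameter_names, case_name)

    def __call__(self, params: ParameterVector) -> StrainResult:
        key = tuple(
            round(params.get(name), self.DECIMALS) for name in self.parameter_names
        )
        try:
            eps = self._lookup[key]
        except KeyError as exc:
            raise KeyError(f"no tabulated strains for vector {key}") from exc
        return StrainResult(epsilon=tuple(eps), load_case=self.case_name)


def write_strain_csv(result: StrainResult, path) -> None:
    pd.DataFrame(
        {
            "case": result.load_case,
            "rib_index": np.arange(1, 25),
            "side": [side for side, _ in RIB_INDEX],
            "rib_level": [level for _, level in RIB_INDEX],
            "epsilon": result.as_array(),
        }
    ).to_csv(path, index=False)


def save_load_case(case: LoadCase, path) -> None:
    payload = {
        "name": case.name,
        "delta_v_kmh": case.delta_v_kmh,
        "load_share": list(case.load_share),
        "load_magnitude": case.load_magnitude,
        "fiber_side": case.fiber_side,
        "shape_mode_weights": list(case.shape_mode_weights),
        "soft_coeffs": dict(case.soft_coeffs),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_load_case(path) -> LoadCase:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return LoadCase(
        name=payload["name"],
        delta_v_kmh=payload["delta_v_kmh"],
        load_share=tuple(payload["load_share"]),
        load_magnitude=payload.get("load_magnitude"),
        fiber_side=payload.get("fiber_side", "cutaneous"),
        shape_mode_weights=tuple(payload.get("shape_mode_weights", DEFAULT_SHAPE_MODE_WEIGHTS)),
        soft_coeffs=payload.get("soft_coeffs", dict(DEFAULT_SOFT_COEFFS)),
    )
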