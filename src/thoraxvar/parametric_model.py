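"""Fifteen-parameter thorax variability space and parametric scaling laws.

Population variability of the thorax is reduced to 15 unitless scaling
coordinates ``s``, each varied over ``[-2, 2]``.  For normally distributed
quantities ``s`` counts standard deviations away from the average-male
baseline; for the costal cartilage modulus ``s`` interpolates the 5th to 95th
percentile of a log-normal modulus distribution; for the three soft-tissue
materials ``s`` interpolates between bounding experimental characterisations
and is weighted uniformly.

The parameters are:

==================  ==========================================================
name                physical meaning
==================  ==========================================================
shape_pc1..6        ribcage shape principal-component scores (SD units)
cort_thickness      multiplicative nodal rib cortical thickness scaling
rib_width           additive rib cross-sectional width offset (minor axis)
rib_height          additive rib cross-sectional height offset (major axis)
cort_material       co-varied bi-linear rib cortical bone parameters
trab_material       co-varied bi-linear rib trabecular bone parameters
cartilage           costal cartilage effective modulus percentile
adipose             subcutaneous adipose Ogden/Prony parameter interpolation
skeletal_muscle     thoracic skeletal muscle parameter interpolation
intercostal_muscle  intercostal muscle parameter interpolation
==================  ==========================================================

All scaling expressions return the printed nominal value at ``s = 0`` (the
cut-point) and are monotone in ``s`` on the admissible range.  Units are kept
exactly as the source literature prints them (GPa / MPa / Pa / kPa mixed);
the material dataclasses carry unit-converting accessors for consumers that
need a single unit system.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Distribution",
    "ParameterSpec",
    "ParameterVector",
    "CorticalMaterial",
    "TrabecularMaterial",
    "CartilageMaterial",
    "SoftTissueMaterial",
    "GeometryScaling",
    "GeometryConvention",
    "PARAMETER_NAMES",
    "S_RANGE_DEFAULT",
    "SIGMA_MU_LOG_THICKNESS",
    "CARTILAGE_SIGMA_S",
    "PER_SD_CONVENTION",
    "RAW_PRINTED_CONVENTION",
    "default_parameter_space",
    "spec_by_name",
    "scale_cortical",
    "scale_trabecular",
    "scale_cartilage",
    "scale_soft_tissue",
    "scale_geometry",
    "bilinear_stress",
    "density_for",
    "sample_parameter",
    "trabecular_g_default",
    "load_parameter_space",
    "save_parameter_space",
    "material_table",
]

#: default admissible range of every scaling coordinate
S_RANGE_DEFAULT: Tuple[float, float] = (-2.0, 2.0)

#: log-space SD of the per-individual cortical thickness level; drives the
#: multiplicative nodal thickness factor exp(sigma_mu * s)
SIGMA_MU_LOG_THICKNESS: float = 0.22

#: s = +/-2 maps the cartilage modulus to its 5th/95th percentile, so the
#: pre-truncation SD of s is 2 / z_{0.95}
CARTILAGE_SIGMA_S: float = 2.0 / float(stats.norm.ppf(0.95))

PARAMETER_NAMES: Tuple[str, ...] = (
    "shape_pc1",
    "shape_pc2",
    "shape_pc3",
    "shape_pc4",
    "shape_pc5",
    "shape_pc6",
    "cort_thickness",
    "rib_width",
    "rib_height",
    "cort_material",
    "trab_material",
    "cartilage",
    "adipose",
    "skeletal_muscle",
    "intercostal_muscle",
)

_UNIFORM_PARAMS = frozenset({"adipose", "skeletal_muscle", "intercostal_muscle"})


class Distribution(str, enum.Enum):
    """Population weighting of a scaling coordinate over its range."""

    STANDARD_NORMAL_TRUNCATED = "standard_normal_truncated"
    UNIFORM = "uniform"
    CARTILAGE_PERCENTILE = "cartilage_percentile"


@dataclass(frozen=True)
class ParameterSpec:
    """One named scaling coordinate with its distribution and range."""

    name: str
    distribution: Distribution
    s_range: Tuple[float, float] = S_RANGE_DEFAULT

    def __post_init__(self) -> None:
        lo, hi = self.s_range
        if not lo < hi:
            raise ValueError(f"{self.name}: s_range lower bound must be < upper")
        object.__setattr__(self, "s_range", (float(lo), float(hi)))
        object.__setattr__(self, "distribution", Distribution(self.distribution))

    def contains(self, s: float) -> bool:
        lo, hi = self.s_range
        return lo <= s <= hi


@dataclass(frozen=True)
class ParameterVector:
    """One scaling-coordinate value per named parameter (unitless)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", {str(k): float(v) for k, v in dict(self.values).items()}
        )

    @classmethod
    def cut_point(cls, space: Sequence[ParameterSpec]) -> "ParameterVector":
        """Baseline vector with every coordinate at s = 0."""
        return cls({spec.name: 0.0 for spec in space})

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(name, default)

    def replace(self, name: str, s: float) -> "ParameterVector":
        if name not in self.values:
            raise KeyError(name)
        new = dict(self.values)
        new[name] = float(s)
        return ParameterVector(new)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.values[name] for name in order], dtype=float)

    def validate(self, space: Sequence[ParameterSpec]) -> None:
        for spec in space:
            s = self.values.get(spec.name)
            if s is None:
                raise ValueError(f"missing coordinate {spec.name!r}")
            if not spec.contains(s):
                raise ValueError(
                    f"{spec.name}={s} outside range {spec.s_range}"
                )


def default_parameter_space() -> Tuple[ParameterSpec, ...]:
    """The 15-coordinate default space.

    Twelve coordinates (shape modes, rib geometry and bone materials) are
    truncated standard normal on [-2, 2]; the cartilage coordinate carries
    the percentile-interpolation weighting; the three soft-tissue
    coordinates are uniform.
    """
    specs = []
    for name in PARAMETER_NAMES:
        if name == "cartilage":
            dist = Distribution.CARTILAGE_PERCENTILE
        elif name in _UNIFORM_PARAMS:
            dist = Distribution.UNIFORM
        else:
            dist = Distribution.STANDARD_NORMAL_TRUNCATED
        specs.append(ParameterSpec(name=name, distribution=dist))
    return tuple(specs)


def spec_by_name(space: Sequence[ParameterSpec], name: str) -> ParameterSpec:
    for spec in space:
        if spec.name == name:
            return spec
    raise KeyError(name)


# ---------------------------------------------------------------------------
# material data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorticalMaterial:
    """Bi-linear rib cortical bone parameters (E, P in GPa; sigma_Y in MPa)."""

    E: float
    sigma_Y: float
    P: float

    def __post_init__(self) -> None:
        if not (self.E > 0 and self.sigma_Y > 0 and self.P > 0):
            raise ValueError("cortical parameters must be strictly positive")
        if not self.P < self.E:
            raise ValueError("plastic modulus must be below elastic modulus")

    @property
    def E_mpa(self) -> float:
        return self.E * 1000.0

    @property
    def sigma_Y_mpa(self) -> float:
        return self.sigma_Y

    @property
    def P_mpa(self) -> float:
        return self.P * 1000.0


@dataclass(frozen=True)
class TrabecularMaterial:
    """Bi-linear rib trabecular bone parameters (all in MPa); g is the shared
    scaling term applied to every field."""

    E: float
    sigma_Y: float
    P: float
    g: float

    def __post_init__(self) -> None:
        if not (self.E > 0 and self.sigma_Y > 0 and self.P > 0):
            raise ValueError("trabecular parameters must be strictly positive")
        if not self.P < self.E:
            raise ValueError("plastic modulus must be below elastic modulus")

    @property
    def E_mpa(self) -> float:
        return self.E

    @property
    def sigma_Y_mpa(self) -> float:
        return self.sigma_Y

    @property
    def P_mpa(self) -> float:
        return self.P


@dataclass(frozen=True)
class CartilageMaterial:
    """Costal cartilage effective modulus, MPa."""

    E_eff: float

    def __post_init__(self) -> None:
        if not self.E_eff > 0:
            raise ValueError("cartilage modulus must be positive")


@dataclass(frozen=True)
class SoftTissueMaterial:
    """Ogden hyper-viscoelastic soft-tissue parameters.

    ``mu`` is the Ogden shear parameter in Pa, ``alpha`` the (fixed) Ogden
    exponent, ``nu`` Poisson's ratio and ``prony`` an ordered tuple of
    ``(beta_i [1/ms], G_i [kPa])`` relaxation terms (empty for muscle).
    """

    tissue: str
    nu: float
    mu: float
    alpha: float
    prony: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.tissue not in ("adipose", "muscle"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")
        if self.tissue == "adipose":
            if len(self.prony) != 3 or any(g <= 0 for _, g in self.prony):
                raise ValueError("adipose Prony series needs 3 positive terms")


@dataclass(frozen=True)
class GeometryScaling:
    """Geometry modifiers: multiplicative nodal thickness factor and additive
    cross-sectional width/height offsets in mm."""

    T_scale: float
    dW: float
    dH: float

    def __post_init__(self) -> None:
        if not self.T_scale > 0:
            raise ValueError("thickness scale factor must be positive")


@dataclass(frozen=True)
class GeometryConvention:
    """Coefficients of the geometry scaling expressions.

    The default treats ``s`` as SD units: width/height change by 1.36 and
    1.96 mm per SD, so s = +/-2 produces the +/-2.7 mm and +/-3.9 mm
    two-SD offsets matching the sixth-rib area-moment variability they were
    derived from.  ``RAW_PRINTED_CONVENTION`` instead applies 2.72 and
    3.92 mm per unit s (the alternative reading of the same expressions).
    """

    width_mm_per_s: float = 1.36
    height_mm_per_s: float = 1.96
    sigma_mu: float = SIGMA_MU_LOG_THICKNESS


PER_SD_CONVENTION = GeometryConvention()
RAW_PRINTED_CONVENTION = GeometryConvention(width_mm_per_s=2.72, height_mm_per_s=3.92)


# ---------------------------------------------------------------------------
# scaling expressions
# ---------------------------------------------------------------------------


def _check_s(s: float, name: str = "s", s_range: Tuple[float, float] = S_RANGE_DEFAULT) -> float:
    s = float(s)
    if not (s_range[0] <= s <= s_range[1]):
        raise ValueError(f"{name}={s} outside admissible range {list(s_range)}")
    return s


def scale_cortical(s: float) -> CorticalMaterial:
    """Co-varied bi-linear cortical bone parameters at scaling coordinate s.

    E = 14.7 + 2.0 s GPa, sigma_Y = 100.7 + 12.9 s MPa, P = 1.94 + 0.5 s GPa.
    """
    s = _check_s(s)
    return CorticalMaterial(E=14.7 + 2.0 * s, sigma_Y=100.7 + 12.9 * s, P=1.94 + 0.5 * s)


def trabecular_g_default(s: float) -> float:
    """Default shared trabecular scaling term g(s) = 0.95 * s / 4.

    This reading keeps all three trabecular parameters positive over
    s in [-2, 2] and covers 95% of the observed parameter range.
    """
    return 0.95 * s / 4.0


def scale_trabecular(
    s: float, g: Callable[[float], float] = trabecular_g_default
) -> TrabecularMaterial:
    """Co-varied bi-linear trabecular bone parameters at s (all MPa).

    E = 25.7 + 46.7 g(s), sigma_Y = 0.42 + 0.65 g(s), P = 5.66 + 11.9 g(s),
    with the shared term g configurable (default ``trabecular_g_default``).
    """
    s = _check_s(s)
    gv = float(g(s))
    E = 25.7 + 46.7 * gv
    sigma_Y = 0.42 + 0.65 * gv
    P = 5.66 + 11.9 * gv
    if min(E, sigma_Y, P) <= 0.0:
        raise ValueError(f"trabecular parameters non-positive at s={s} (g={gv})")
    return TrabecularMaterial(E=E, sigma_Y=sigma_Y, P=P, g=gv)


def scale_cartilage(s: float) -> CartilageMaterial:
    """Costal cartilage effective modulus E = 21.4 + 1.15 s^2 + 9.05 s MPa.

    The quadratic interpolates the 5th to 95th percentile of a log-normal
    modulus distribution with sample mean 21.4 MPa and SD 12.0 MPa as s runs
    from -2 to +2; the derivative 2*1.15*s + 9.05 is positive on [-2, 2], so
    the expression is monotone.
    """
    s = _check_s(s)
    return CartilageMaterial(E_eff=21.4 + 1.15 * s * s + 9.05 * s)


_MUSCLE_ALIASES = {"muscle", "skeletal_muscle", "intercostal_muscle"}


def scale_soft_tissue(tissue: str, s: float) -> SoftTissueMaterial:
    """Soft-tissue Ogden/Prony parameters at s.

    ``tissue`` is "adipose" or "muscle" ("skeletal_muscle" and
    "intercostal_muscle" are accepted aliases for the shared muscle model).
    """
    s = _check_s(s)
    if tissue == "adipose":
        nu = 0.499996 - 1.6216 * math.exp(-1.2951 * s) * 1e-5
        return SoftTissueMaterial(
            tissue="adipose",
            nu=nu,
            mu=35.0 + 3.0 * s,
            alpha=20.0,
            prony=(
                (0.006, 0.80 + 0.12 * s),
                (0.05, 1.80 + 0.27 * s),
                (0.6, 2.22 + 0.34 * s),
            ),
        )
    if tissue in _MUSCLE_ALIASES:
        return SoftTissueMaterial(tissue="muscle", nu=0.495, mu=108.0 + 22.5 * s, alpha=13.2)
    raise ValueError(f"unknown tissue {tissue!r}")


def scale_geometry(
    s_thickness: float,
    s_width: float,
    s_height: float,
    convention: GeometryConvention = PER_SD_CONVENTION,
) -> GeometryScaling:
    """Geometry modifiers for the three geometric scaling coordinates.

    The thickness factor exp(sigma_mu * s) multiplies every nodal cortical
    thickness of all 24 ribs simultaneously; width/height offsets are added
    to the nominal cross-sectional dimensions along the whole rib span.
    """
    s_thickness = _check_s(s_thickness, "s_thickness")
    s_width = _check_s(s_width, "s_width")
    s_height = _check_s(s_height, "s_height")
    return GeometryScaling(
        T_scale=math.exp(convention.sigma_mu * s_thickness),
        dW=convention.width_mm_per_s * s_width,
        dH=convention.height_mm_per_s * s_height,
    )


def bilinear_stress(material, strain):
    """Tension-side bi-linear stress (MPa) for a cortical or trabecular
    material at the given engineering strain.

    Elastic up to the yield strain sigma_Y/E, hardening with slope P beyond;
    continuous at yield.  Accepts scalar or array strain; negative strain is
    rejected (the curve models the tension side only).
    """
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0):
        raise ValueError("strain must be non-negative")
    E = material.E_mpa
    sy = material.sigma_Y_mpa
    P = material.P_mpa
    eps_y = sy / E
    stress = np.where(strain <= eps_y, E * strain, sy + P * (strain - eps_y))
    return float(stress) if stress.ndim == 0 else stress


# ---------------------------------------------------------------------------
# population weighting
# ---------------------------------------------------------------------------


def density_for(s, spec: ParameterSpec):
    """Probability density of the scaling coordinate at s under its spec.

    Truncated standard normal (renormalised over the spec range) for normal
    coordinates, the flat 1/(b-a) density for uniform coordinates, and for
    the cartilage percentile coordinate a normal with SD 2/z_{0.95}
    truncated to the range (so that s = +/-2 corresponds to the 5th/95th
    modulus percentiles before truncation).  Integrates to 1 over s_range.
    """
    arr = np.asarray(s, dtype=float)
    lo, hi = spec.s_range
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"s outside {spec.name} range {spec.s_range}")
    if spec.distribution is Distribution.UNIFORM:
        dens = np.full_like(arr, 1.0 / (hi - lo))
    elif spec.distribution is Distribution.STANDARD_NORMAL_TRUNCATED:
        z = stats.norm.cdf(hi) - stats.norm.cdf(lo)
        dens = stats.norm.pdf(arr) / z
    elif spec.distribution is Distribution.CARTILAGE_PERCENTILE:
        sc = CARTILAGE_SIGMA_S
        z = stats.norm.cdf(hi, scale=sc) - stats.norm.cdf(lo, scale=sc)
        dens = stats.norm.pdf(arr, scale=sc) / z
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unhandled distribution {spec.distribution}")
    return float(dens) if dens.ndim == 0 else dens


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Random draws of one coordinate under its population distribution."""
    lo, hi = spec.s_range
    u = rng.uniform(size=size)
    if spec.distribution is Distribution.UNIFORM:
        return lo + (hi - lo) * u
    if spec.distribution is Distribution.STANDARD_NORMAL_TRUNCATED:
        scale = 1.0
    else:
        scale = CARTILAGE_SIGMA_S
    c_lo = stats.norm.cdf(lo, scale=scale)
    c_hi = stats.norm.cdf(hi, scale=scale)
    return stats.norm.ppf(c_lo + (c_hi - c_lo) * u, scale=scale)


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------


def save_parameter_space(space: Sequence[ParameterSpec], path) -> None:
    """Write a parameter-space definition file (YAML)."""
    payload = {
        "parameters": [
            {
                "name": spec.name,
                "distribution": spec.distribution.value,
                "s_range": list(spec.s_range),
            }
            for spec in space
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_parameter_space(path) -> Tuple[ParameterSpec, ...]:
    """Read a parameter-space definition file written by
    :func:`save_parameter_space`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return tuple(
        ParameterSpec(
            name=entry["name"],
            distribution=Distribution(entry["distribution"]),
            s_range=tuple(entry.get("s_range", S_RANGE_DEFAULT)),
        )
        for entry in payload["parameters"]
    )


def material_table(s_values: Iterable[float] = (-2.0, -1.0, 0.0, 1.0, 2.0)) -> pd.DataFrame:
    """Tabulate every parametric expression at the given s values.

    Returns a tidy frame with columns (parameter, s, field, value, unit).
    """
    rows = []

    def add(parameter, s, field, value, unit):
        rows.append(
            {"parameter": parameter, "s": s, "field": field, "value": value, "unit": unit}
        )

    for s in s_values:
        cort = scale_cortical(s)
        add("cort_material", s, "E", cort.E, "GPa")
        add("cort_material", s, "sigma_Y", cort.sigma_Y, "MPa")
        add("cort_material", s, "P", cort.P, "GPa")
        trab = scale_trabecular(s)
        add("trab_material", s, "E", trab.E, "MPa")
        add("trab_material", s, "sigma_Y", trab.sigma_Y, "MPa")
        add("trab_material", s, "P", trab.P, "MPa")
        add("cartilage", s, "E_eff", scale_cartilage(s).E_eff, "MPa")
        adi = scale_soft_tissue("adipose", s)
        add("adipose", s, "nu", adi.nu, "-")
        add("adipose", s, "mu", adi.mu, "Pa")
        add("adipose", s, "alpha", adi.alpha, "-")
        for k, (beta, G) in enumerate(adi.prony, start=1):
            add("adipose", s, f"G{k}", G, "kPa")
            add("adipose", s, f"beta{k}", beta, "1/ms")
        mus = scale_soft_tissue("muscle", s)
        add("muscle", s, "nu", mus.nu, "-")
        add("muscle", s, "mu", mus.mu, "Pa")
        add("muscle", s, "alpha", mus.alpha, "-")
        geo = scale_geometry(s, s, s)
        add("cort_thickness", s, "T_scale", geo.T_scale, "-")
        add("rib_width", s, "dW", geo.dW, "mm")
        add("rib_height", s, "dH", geo.dH, "mm")
    return pd.DataFrame(rows, columns=["parameter", "s", "field", "value", "unit"])
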