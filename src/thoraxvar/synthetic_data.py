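"""Synthetic inputs with the statistical structure the pipeline assumes.

Real rib centroidal curves come from CT reconstructions and are proprietary;
this module generates statistical stand-ins so every stage of the pipeline
is testable without any download.  Generated populations always come with a
ground-truth sidecar (the generating modes, scores and distribution
parameters) so recovery tests never have to go through the code under test.

Three generators are provided:

* rib centroidal curves / ribcage populations: a smooth parametric arc per
  rib level (semi-elliptical span with level-dependent size, droop and a
  small out-of-plane twist), plus population variation as a known set of
  orthonormal coordinate-space modes with independent normal scores and
  isotropic residual noise -- exactly the correlated, PCA-compatible
  structure a statistical shape model expects;
* cortical thickness maps: per-subject log-normal nodal thickness with the
  subject log-mean itself normal across subjects (SD 0.22 by default), the
  two-level structure behind the parametric thickness scaling;
* analytic sensitivity test functions (multiplicative, additive-linear,
  Ishigami, constant) with their exact Sobol indices attached, for
  validating the M-DRM and Monte-Carlo estimators.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .parametric_model import Distribution, ParameterSpec
from .shape_model import (
    CURVE_ORDER,
    RibCurve,
    RibcageGeometry,
    SubjectMeta,
    ThicknessMap,
)

__all__ = [
    "GeneratorConfig",
    "TestFunction",
    "generate_rib_curve",
    "generate_population",
    "generate_thickness_maps",
    "make_test_functions",
    "population_hash",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic generators.

    ``n_subjects`` mirrors the 89-strong average-male shape sample and
    ``n_thickness_subjects`` the 33 thickness-mapped individuals the
    analysis emulates; ``mu_sd`` is the across-subject SD of the log-mean
    thickness (0.22).  Metadata windows deliberately extend beyond the
    average-male inclusion criteria so the filter has something to reject.
    """

    seed: int = 0
    n_subjects: int = 89
    rib_points: int = 20
    mode_sds: Tuple[float, ...] = (30.0, 22.0, 16.0, 11.0, 8.0, 6.0)  # mm
    noise_sd: float = 0.08  # mm, per coordinate; sub-voxel digitisation-scale
    # residual, small enough that the generating mode subspace stays
    # identifiable from n_subjects samples in the ~1400-dim coordinate space
    n_thickness_subjects: int = 33
    n_nodes: int = 2000
    pop_log_mean: float = math.log(0.7)  # log-mm; ~0.7 mm nominal thickness
    mu_sd: float = 0.22  # across-subject SD of the log-mean
    within_sigma: float = 0.35  # within-subject log-SD
    age_range: Tuple[float, float] = (16.0, 60.0)
    height_range: Tuple[float, float] = (1.68, 1.86)
    weight_range: Tuple[float, float] = (68.0, 86.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if any(sd < 0 for sd in self.mode_sds) or self.noise_sd < 0 or self.mu_sd < 0:
            raise ValueError("SDs must be non-negative")


# per-level arc geometry: lateral semi-span, antero-posterior semi-depth (mm)
_SPAN = (55.0, 75.0, 92.0, 105.0, 115.0, 122.0, 126.0, 124.0, 118.0, 108.0, 95.0, 80.0)
_DEPTH = (40.0, 55.0, 68.0, 78.0, 85.0, 90.0, 92.0, 90.0, 86.0, 80.0, 72.0, 62.0)
_SWEEP = 0.85 * math.pi  # angular extent of the arc


def generate_rib_curve(level: int, side: str, n_points: int = 20) -> RibCurve:
    """Template centroidal curve for one rib.

    A planar-ish semi-elliptical arc from the vertebral end (posterior)
    around to the anterior end, with level-dependent span and depth, a
    pump-handle droop that grows caudally, and a small out-of-plane twist;
    the left curve is the mirror image of the right about the sagittal
    plane.  Deterministic.
    """
    if not 1 <= level <= 12:
        raise ValueError("level must be 1..12")
    if side not in ("left", "right"):
        raise ValueError("side must be left or right")
    span = _SPAN[level - 1]
    depth = _DEPTH[level - 1]
    droop = 10.0 + 2.0 * level  # mm of caudal droop over the arc
    z0 = -18.0 * level
    t = np.linspace(0.0, _SWEEP, n_points)
    sign = -1.0 if side == "left" else 1.0
    x = sign * span * np.sin(t)
    y = -depth * np.cos(t)
    z = z0 - droop * (1.0 - np.cos(t)) + 2.0 * np.sin(2.0 * t)
    return RibCurve(rib_level=level, side=side, points=np.column_stack([x, y, z]))


def _template_vector(n_points: int) -> Tuple[np.ndarray, Tuple[int, ...]]:
    curves = [generate_rib_curve(level, side, n_points) for side, level in CURVE_ORDER]
    vec = np.concatenate([c.points.ravel() for c in curves])
    return vec, tuple(c.n_points for c in curves)


def _ground_truth_modes(d: int, q: int) -> np.ndarray:
    """q smooth, deterministic, orthonormal coordinate-space modes (q, d)."""
    idx = np.arange(d)
    raw = np.stack(
        [np.sin(2.0 * math.pi * (j + 1) * idx / d + 0.37 * j) for j in range(q)]
    )
    # orthonormalise; smoothness is kept, exact directions recorded as truth
    Q, _ = np.linalg.qr(raw.T)
    return Q.T[:q]


def generate_population(
    config: GeneratorConfig = GeneratorConfig(),
) -> Tuple[List[RibcageGeometry], Dict[str, object]]:
    """Sample a ribcage population with known generating structure.

    Subjects are template + sum_j sigma_j z_ij M_j + isotropic noise, with
    independent standard-normal scores z.  Metadata (age, height, weight)
    is sampled uniformly over windows wider than the average-male criteria.
    Returns the population and a ground-truth dict (modes, scores, SDs,
    metadata) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    template, counts = _template_vector(config.rib_points)
    d = template.size
    q = len(config.mode_sds)
    modes = _ground_truth_modes(d, q)
    sds = np.asarray(config.mode_sds, dtype=float)
    scores = rng.standard_normal((config.n_subjects, q)) * sds
    noise = rng.standard_normal((config.n_subjects, d)) * config.noise_sd
    X = template + scores @ modes + noise
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    heights = rng.uniform(*config.height_range, size=config.n_subjects)
    weights = rng.uniform(*config.weight_range, size=config.n_subjects)
    population = [
        RibcageGeometry.from_vector(
            X[i],
            counts,
            SubjectMeta(
                subject_id=f"synth{i:04d}",
                age_years=float(ages[i]),
                height_m=float(heights[i]),
                weight_kg=float(weights[i]),
            ),
        )
        for i in range(config.n_subjects)
    ]
    truth = {
        "template": template,
        "point_counts": counts,
        "modes": modes,
        "mode_sds": sds,
        "scores": scores,
        "noise_sd": config.noise_sd,
        "metadata": {
            "age_years": ages,
            "height_m": heights,
            "weight_kg": weights,
        },
        "seed": config.seed,
    }
    return population, truth


def generate_thickness_maps(
    config: GeneratorConfig = GeneratorConfig(),
) -> Tuple[List[ThicknessMap], Dict[str, object]]:
    """Two-level log-normal cortical thickness maps.

    Subject j draws a log-mean mu_j ~ N(pop_log_mean, mu_sd) and nodal
    thicknesses T ~ exp(N(mu_j, within_sigma)).  Returns the maps and the
    generating mu_j values as truth.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    mus = rng.normal(config.pop_log_mean, config.mu_sd, size=config.n_thickness_subjects)
    maps = []
    for j, mu in enumerate(mus):
        thickness = np.exp(rng.normal(mu, config.within_sigma, size=config.n_nodes))
        maps.append(
            ThicknessMap(
                node_ids=np.arange(config.n_nodes),
                thickness=thickness,
                subject_id=f"thick{j:03d}",
            )
        )
    truth = {
        "mu_log": mus,
        "pop_log_mean": config.pop_log_mean,
        "mu_sd": config.mu_sd,
        "within_sigma": config.within_sigma,
        "seed": config.seed,
    }
    return maps, truth


# ---------------------------------------------------------------------------
# analytic test functions for the sensitivity estimators
# ---------------------------------------------------------------------------


@dataclass
class TestFunction:
    """A vectorised black-box with its exact Sobol indices attached.

    ``f`` accepts an (m, n) array (columns in ``space`` order) or a length-n
    vector.  ``cut_point`` is the reference point for M-DRM designs (the
    input mean where that is non-degenerate for the product form).
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    space: Tuple[ParameterSpec, ...]
    cut_point: np.ndarray
    S_analytic: np.ndarray
    S_T_analytic: np.ndarray

    @property
    def n_dim(self) -> int:
        return len(self.space)

    def cut_vector(self):
        from .parametric_model import ParameterVector

        return ParameterVector(
            {spec.name: float(c) for spec, c in zip(self.space, self.cut_point)}
        )

    def scalar_model(self) -> Callable:
        """Adapter for ParameterVector-based design builders."""
        names = [spec.name for spec in self.space]

        def call(pv) -> float:
            out = np.asarray(self.f(np.array([pv.get(n) for n in names])))
            return float(out.reshape(-1)[0])

        return call


def _uniform_space(n: int, lo: float, hi: float) -> Tuple[ParameterSpec, ...]:
    return tuple(
        ParameterSpec(name=f"x{i + 1}", distribution=Distribution.UNIFORM, s_range=(lo, hi))
        for i in range(n)
    )


def make_test_functions() -> Dict[str, TestFunction]:
    """The analytic validation battery for the sensitivity estimators.

    * ``multiplicative``: h(x) = prod(1 + a_i x_i), x_i ~ U(-1, 1).  Sobol
      indices have the closed form S_i = (r_i - 1)/(prod r - 1) with
      r_i = 1 + a_i^2/3; the product form is exact here.
    * ``additive``: h(x) = c0 + sum a_i x_i with truncated-normal inputs;
      S_i = S_Ti = a_i^2 / sum a_k^2 (the input variance cancels).
    * ``ishigami``: the standard strongly-interacting benchmark on
      U(-pi, pi)^3 with a = 7, b = 0.1.  Its mean is a degenerate cut-point
      for the product form (every one-dimensional cut through the origin is
      identically zero), so the attached cut-point is the half-range
      midpoint (pi/2, pi/2, pi/2).
    * ``constant``: all indices zero.
    """
    funcs: Dict[str, TestFunction] = {}

    # multiplicative ---------------------------------------------------
    a_mult = np.array([0.6, 0.4, 0.25, 0.15])

    def f_mult(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.prod(1.0 + a_mult * X, axis=1)

    r = 1.0 + a_mult**2 / 3.0
    prod_r = float(np.prod(r))
    S_mult = (r - 1.0) / (prod_r - 1.0)
    S_T_mult = np.array(
        [(prod_r / r[i]) * (r[i] - 1.0) / (prod_r - 1.0) for i in range(a_mult.size)]
    )
    funcs["multiplicative"] = TestFunction(
        name="multiplicative",
        f=f_mult,
        space=_uniform_space(a_mult.size, -1.0, 1.0),
        cut_point=np.zeros(a_mult.size),
        S_analytic=S_mult,
        S_T_analytic=S_T_mult,
    )

    # additive ---------------------------------------------------------
    a_add = np.array([1.0, 2.0, 3.0])
    c0 = 10.0

    def f_add(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return c0 + X @ a_add

    S_add = a_add**2 / float(np.sum(a_add**2))
    funcs["additive"] = TestFunction(
        name="additive",
        f=f_add,
        space=tuple(
            ParameterSpec(
                name=f"x{i + 1}",
                distribution=Distribution.STANDARD_NORMAL_TRUNCATED,
                s_range=(-2.0, 2.0),
            )
            for i in range(a_add.size)
        ),
        cut_point=np.zeros(a_add.size),
        S_analytic=S_add,
        S_T_analytic=S_add.copy(),
    )

    # Ishigami ----------------------------------------------------------
    a_ish, b_ish = 7.0, 0.1

    def f_ish(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (
            np.sin(X[:, 0])
            + a_ish * np.sin(X[:, 1]) ** 2
            + b_ish * X[:, 2] ** 4 * np.sin(X[:, 0])
        )

    pi4 = math.pi**4
    pi8 = math.pi**8
    V1 = 0.5 * (1.0 + b_ish * pi4 / 5.0) ** 2
    V2 = a_ish**2 / 8.0
    V13 = b_ish**2 * pi8 * (1.0 / 18.0 - 1.0 / 50.0)
    V = V1 + V2 + V13
    S_ish = np.array([V1 / V, V2 / V, 0.0])
    S_T_ish = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    funcs["ishigami"] = TestFunction(
        name="ishigami",
        f=f_ish,
        space=_uniform_space(3, -math.pi, math.pi),
        cut_point=np.array([math.pi / 2.0, math.pi / 2.0, math.pi / 2.0]),
        S_analytic=S_ish,
        S_T_analytic=S_T_ish,
    )

    # constant -----------------------------------------------------------
    def f_const(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], 3.0)

    funcs["constant"] = TestFunction(
        name="constant",
        f=f_const,
        space=_uniform_space(3, -1.0, 1.0),
        cut_point=np.zeros(3),
        S_analytic=np.zeros(3),
        S_T_analytic=np.zeros(3),
    )
    return funcs


# ---------------------------------------------------------------------------
# reproducibility helpers
# ---------------------------------------------------------------------------


def population_hash(population: Sequence[RibcageGeometry]) -> str:
    """Stable hash of a serialised population (reproducibility check)."""
    h = hashlib.sha256()
    for subject in population:
        h.update(subject.meta.subject_id.encode())
        h.update(np.ascontiguousarray(subject.coord_vector()).tobytes())
    return h.hexdigest()


def write_truth_sidecar(truth: Dict[str, object], path) -> None:
    """Write generating parameters next to the data (`*.truth.json`)."""

    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(convert(truth), indent=2))
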