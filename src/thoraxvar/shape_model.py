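"""Statistical shape model of rib centroidal curves and cortical thickness.

The ribcage of a subject is represented by 24 centroidal curves (12 rib
levels, left and right), each an ordered polyline of 3-D points in mm with
the vertebral end first.  A population of such ribcages, filtered to
average-male anthropometry, is summarised by principal component analysis of
the stacked point coordinates: new ribcage geometries are generated along a
single component ``i`` as

    C_i(s) = mu + P_i * sigma_i * s

where ``mu`` is the mean coordinate vector, ``P_i`` the unit component and
``sigma_i`` the sample SD of the training scores, so ``s`` is in SD units.

Rib cortical bone thickness maps (one thickness per mesh node) are fitted by
per-subject log-normal distributions; the spread of the fitted log-means
across subjects gives the sigma_mu scaling range used by the parametric
thickness expression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RibCurve",
    "SubjectMeta",
    "RibcageGeometry",
    "ShapeModel",
    "ThicknessMap",
    "LogNormalFit",
    "select_average_males",
    "fit_shape_pca",
    "generate_ribcage",
    "fit_thickness_lognormal",
    "population_mu_sd",
    "read_population_csv",
    "write_population_csv",
    "save_shape_model",
    "load_shape_model",
    "export_morph_targets",
]

SIDES = ("left", "right")

# average-male inclusion window: strict >18 years, closed height/weight bands
AGE_MIN_EXCLUSIVE = 18.0
HEIGHT_RANGE_M = (1.72, 1.82)
WEIGHT_RANGE_KG = (72.0, 82.0)


@dataclass
class RibCurve:
    """Centroidal curve of one rib: ordered 3-D points, vertebral end first."""

    rib_level: int
    side: str
    points: np.ndarray  # (n, 3), mm

    def __post_init__(self) -> None:
        if not 1 <= int(self.rib_level) <= 12:
            raise ValueError("rib_level must be 1..12")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("points must be an (n>=2, 3) array")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive curve points must be distinct")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class SubjectMeta:
    subject_id: str
    age_years: Optional[float] = None
    height_m: Optional[float] = None
    weight_kg: Optional[float] = None

    def complete(self) -> bool:
        return None not in (self.age_years, self.height_m, self.weight_kg)


#: canonical curve order used when flattening a ribcage to one vector
CURVE_ORDER: Tuple[Tuple[str, int], ...] = tuple(
    (side, level) for side in SIDES for level in range(1, 13)
)


@dataclass
class RibcageGeometry:
    """24 rib curves plus subject metadata."""

    curves: List[RibCurve]
    meta: SubjectMeta

    def __post_init__(self) -> None:
        if len(self.curves) != 24:
            raise ValueError("a ribcage needs exactly 24 curves")
        keyed = {(c.side, c.rib_level): c for c in self.curves}
        if len(keyed) != 24:
            raise ValueError("duplicate (side, level) curves")
        self.curves = [keyed[key] for key in CURVE_ORDER]

    def point_counts(self) -> Tuple[int, ...]:
        return tuple(c.n_points for c in self.curves)

    def coord_vector(self) -> np.ndarray:
        """Flatten all curves (canonical order, row-major points) to 1-D."""
        return np.concatenate([c.points.ravel() for c in self.curves])

    @classmethod
    def from_vector(
        cls,
        vector: np.ndarray,
        point_counts: Sequence[int],
        meta: Optional[SubjectMeta] = None,
    ) -> "RibcageGeometry":
        vector = np.asarray(vector, dtype=float)
        curves = []
        offset = 0
        for (side, level), n in zip(CURVE_ORDER, point_counts):
            block = vector[offset : offset + 3 * n].reshape(n, 3)
            curves.append(RibCurve(rib_level=level, side=side, points=block))
            offset += 3 * n
        if offset != vector.size:
            raise ValueError("vector length inconsistent with point counts")
        return cls(curves=curves, meta=meta or SubjectMeta(subject_id="generated"))


def select_average_males(population: Sequence[RibcageGeometry]) -> List[RibcageGeometry]:
    """Subjects with age > 18 years, height 1.72-1.82 m, weight 72-82 kg.

    Height and weight bounds are closed; the age bound is strict.  Subjects
    with missing metadata are excluded with a logged warning.
    """
    selected = []
    for subject in population:
        m = subject.meta
        if not m.complete():
            logger.warning("subject %s excluded: incomplete metadata", m.subject_id)
            continue
        if (
            m.age_years > AGE_MIN_EXCLUSIVE
            and HEIGHT_RANGE_M[0] <= m.height_m <= HEIGHT_RANGE_M[1]
            and WEIGHT_RANGE_KG[0] <= m.weight_kg <= WEIGHT_RANGE_KG[1]
        ):
            selected.append(subject)
    return selected


@dataclass
class ShapeModel:
    """PCA summary of a ribcage population.

    ``components`` holds k orthonormal rows; ``sigma`` the per-component
    sample SD (n-1 denominator) of the training scores in mm;
    ``explained_variance`` the fraction of total training variance per
    component.  ``point_counts`` records the curve template needed to
    reshape generated vectors back into 24 rib curves.
    """

    mu: np.ndarray  # (d,)
    components: np.ndarray  # (k, d), orthonormal rows
    sigma: np.ndarray  # (k,)
    explained_variance: np.ndarray  # (k,)
    point_counts: Tuple[int, ...]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.sigma) > 1e-12):
            raise ValueError("component score SDs must be non-increasing")
        if self.explained_variance.sum() > 1.0 + 1e-9:
            raise ValueError("explained variance fractions must sum to <= 1")

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def project(self, vector: np.ndarray) -> np.ndarray:
        """Scores of a coordinate vector on all components (mm)."""
        return self.components @ (np.asarray(vector, dtype=float) - self.mu)

    def to_geometry(self, vector: np.ndarray, subject_id: str = "generated") -> RibcageGeometry:
        return RibcageGeometry.from_vector(
            vector, self.point_counts, SubjectMeta(subject_id=subject_id)
        )


def fit_shape_pca(sample: Sequence[RibcageGeometry], k: int) -> ShapeModel:
    """Mean-centred PCA of a ribcage sample, keeping k components.

    Components are ordered by decreasing score variance and sign-fixed so
    the largest-magnitude loading of each component is positive (PCA sign is
    otherwise arbitrary).  Score SDs use the n-1 denominator.
    """
    if len(sample) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} subjects, got {len(sample)}")
    counts = sample[0].point_counts()
    for subject in sample:
        if subject.point_counts() != counts:
            raise ValueError("inconsistent point counts across subjects")
    X = np.stack([subject.coord_vector() for subject in sample])
    n = X.shape[0]
    mu = X.mean(axis=0)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive
    for j in range(Vt.shape[0]):
        idx = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, idx] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total_var = float(np.sum(S**2))
    sigma = S[:k] / np.sqrt(n - 1)
    if total_var > 0:
        explained = (S[:k] ** 2) / total_var
    else:
        explained = np.zeros(k)
    return ShapeModel(
        mu=mu,
        components=Vt[:k],
        sigma=sigma,
        explained_variance=explained,
        point_counts=counts,
    )


def generate_ribcage(model: ShapeModel, i: int, s: float) -> np.ndarray:
    """Coordinate vector mu + P_i * sigma_i * s for component i (1-based).

    ``s`` is in SD units of the training scores and must lie in [-2, 2].
    Use :meth:`ShapeModel.to_geometry` to reshape into 24 rib curves.
    """
    if not 1 <= i <= model.k:
        raise IndexError(f"component index {i} outside 1..{model.k}")
    if not -2.0 <= s <= 2.0:
        raise ValueError("s must lie in [-2, 2]")
    return model.mu + model.components[i - 1] * model.sigma[i - 1] * float(s)


# ---------------------------------------------------------------------------
# cortical thickness maps
# ---------------------------------------------------------------------------


@dataclass
class ThicknessMap:
    """Nodal cortical thickness map of one subject (mm, all positive)."""

    node_ids: np.ndarray
    thickness: np.ndarray
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.node_ids.shape[0] != self.thickness.shape[0]:
            raise ValueError("node_ids and thickness must align")
        if np.any(self.thickness <= 0):
            raise ValueError("thickness values must be positive")


@dataclass
class LogNormalFit:
    """Log-normal fit of a thickness map: location and scale in log space."""

    mu_log: float
    sigma_log: float
    n_nodes: int
    degenerate: bool = False


def fit_thickness_lognormal(tmap: ThicknessMap) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of one thickness map.

    The log-moment estimators (mean and ML standard deviation of log T) are
    the exact MLE for the log-normal, so the fit is deterministic.  A map of
    identical values yields sigma_log = 0 and is flagged degenerate.
    """
    if tmap.thickness.shape[0] < 10:
        raise ValueError("need at least 10 nodes for a thickness fit")
    logt = np.log(tmap.thickness)
    mu = float(np.mean(logt))
    sigma = float(np.std(logt))  # MLE (ddof=0)
    degenerate = sigma == 0.0
    if degenerate:
        warnings.warn(f"degenerate thickness map for {tmap.subject_id}: sigma_log=0")
    return LogNormalFit(mu_log=mu, sigma_log=sigma, n_nodes=tmap.thickness.shape[0], degenerate=degenerate)


def population_mu_sd(fits: Sequence[LogNormalFit]) -> float:
    """Sample SD (n-1) of the fitted log-means across subjects.

    This is the sigma_mu feeding the parametric thickness scaling.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    return float(np.std([f.mu_log for f in fits], ddof=1))


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------


def write_population_csv(
    population: Sequence[RibcageGeometry], curves_path, meta_path
) -> None:
    rows = []
    for subject in population:
        for curve in subject.curves:
            for p, (x, y, z) in enumerate(curve.points):
                rows.append(
                    (subject.meta.subject_id, curve.rib_level, curve.side, p, x, y, z)
                )
    pd.DataFrame(
        rows,
        columns=["subject_id", "rib_level", "side", "point_index", "x_mm", "y_mm", "z_mm"],
    ).to_csv(curves_path, index=False)
    pd.DataFrame(
        [
            (s.meta.subject_id, s.meta.age_years, s.meta.height_m, s.meta.weight_kg)
            for s in population
        ],
        columns=["subject_id", "age_years", "height_m", "weight_kg"],
    ).to_csv(meta_path, index=False)


def read_population_csv(curves_path, meta_path) -> List[RibcageGeometry]:
    curves = pd.read_csv(curves_path)
    meta = pd.read_csv(meta_path).set_index("subject_id")
    population = []
    for subject_id, sub in curves.groupby("subject_id", sort=False):
        rib_curves = []
        for (level, side), block in sub.groupby(["rib_level", "side"], sort=False):
            block = block.sort_values("point_index")
            rib_curves.append(
                RibCurve(
                    rib_level=int(level),
                    side=str(side),
                    points=block[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                )
            )
        row = meta.loc[subject_id]
        population.append(
            RibcageGeometry(
                curves=rib_curves,
                meta=SubjectMeta(
                    subject_id=str(subject_id),
                    age_years=None if pd.isna(row["age_years"]) else float(row["age_years"]),
                    height_m=None if pd.isna(row["height_m"]) else float(row["height_m"]),
                    weight_kg=None if pd.isna(row["weight_kg"]) else float(row["weight_kg"]),
                ),
            )
        )
    return population


def save_shape_model(model: ShapeModel, directory) -> None:
    """Archive a shape model as a JSON header plus CSV matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "k": model.k,
        "sigma_mm": model.sigma.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "point_counts": list(model.point_counts),
    }
    (directory / "model.json").write_text(json.dumps(header, indent=2))
    pd.DataFrame({"mu_mm": model.mu}).to_csv(directory / "mu.csv", index=False)
    pd.DataFrame(
        model.components.T, columns=[f"pc{j + 1}" for j in range(model.k)]
    ).to_csv(directory / "components.csv", index=False)


def load_shape_model(directory) -> ShapeModel:
    directory = Path(directory)
    header = json.loads((directory / "model.json").read_text())
    mu = pd.read_csv(directory / "mu.csv")["mu_mm"].to_numpy()
    components = pd.read_csv(directory / "components.csv").to_numpy().T
    return ShapeModel(
        mu=mu,
        components=components,
        sigma=np.asarray(header["sigma_mm"]),
        explained_variance=np.asarray(header["explained_variance"]),
        point_counts=tuple(header["point_counts"]),
    )


def export_morph_targets(
    model: ShapeModel,
    directory,
    components: Sequence[int],
    s_values: Sequence[float],
) -> List[Path]:
    """Write per-(component, s) CSVs of target rib-curve coordinates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i in components:
        for s in s_values:
            geom = model.to_geometry(generate_ribcage(model, i, s))
            rows = []
            for curve in geom.curves:
                for p, (x, y, z) in enumerate(curve.points):
                    rows.append((curve.rib_level, curve.side, p, x, y, z))
            path = directory / f"morph_pc{i}_s{s:+.2f}.csv"
            pd.DataFrame(
                rows, columns=["rib_level", "side", "point_index", "x_mm", "y_mm", "z_mm"]
            ).to_csv(path, index=False)
            written.append(path)
    return written
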