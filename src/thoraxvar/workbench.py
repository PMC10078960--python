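"""End-to-end orchestration of the two-case sensitivity study.

``run_study`` wires the pieces together: calibrate both load cases so the
cut-point model predicts the anchor NFR2+ risk, build the one-at-a-time
Gauss design per case (n * N_GP + 1 surrogate evaluations each), compute
M-DRM sensitivity indices, and write the design/index/interaction CSVs plus
a ranked JSON summary and a plain-text run log.  The pipeline contains no
random state, so a rerun with the same config reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .parametric_model import (
    ParameterSpec,
    ParameterVector,
    default_parameter_space,
)
from .risk_model import (
    DEFAULT_AGE_YEARS,
    DEFAULT_RISK_FUNCTION,
    RiskFunction,
    nfr2plus,
    rib_fracture_probability,
)
from .sensitivity import run_sensitivity_study, write_index_report
from .surrogate import LoadCase, calibrate_load, default_load_case, peak_rib_strain

__all__ = ["StudyConfig", "StudyReport", "run_study", "factorial_cost", "risk_model_for_case"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one two-case sensitivity study.

    ``target_risk`` is the calibration anchor for the cut-point NFR2+ of
    both load cases; ``seed`` is reserved for Monte-Carlo oracle runs (the
    main pipeline is deterministic).
    """

    load_cases: Tuple[str, ...] = ("frontal", "near_side")
    n_gp: int = 5
    age_years: float = DEFAULT_AGE_YEARS
    target_risk: float = 0.51
    risk_function: RiskFunction = DEFAULT_RISK_FUNCTION
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gp < 2:
            raise ValueError("N_GP must be >= 2")


@dataclass
class StudyReport:
    """Everything run_study produced, plus the paths it wrote."""

    config: StudyConfig
    space: Tuple[ParameterSpec, ...]
    calibrated_cases: Dict[str, LoadCase]
    cases: Dict[str, Dict[str, object]]
    paths: Dict[str, object] = field(default_factory=dict)

    def ranking(self, case: str):
        return self.cases[case]["result"].ranking()

    def n_evaluations(self, case: str) -> int:
        return self.cases[case]["n_evaluations"]


def risk_model_for_case(
    case: LoadCase,
    age: float = DEFAULT_AGE_YEARS,
    rf: RiskFunction = DEFAULT_RISK_FUNCTION,
):
    """Black-box ParameterVector -> NFR2+ model for one calibrated case."""

    def model(params: ParameterVector) -> float:
        eps = peak_rib_strain(params, case).as_array()
        return nfr2plus(rib_fracture_probability(eps, age=age, rf=rf))

    return model


def run_study(
    config: StudyConfig = StudyConfig(),
    space: Optional[Sequence[ParameterSpec]] = None,
) -> StudyReport:
    """Calibrate, design, analyse and (optionally) write the full study."""
    space = tuple(space) if space is not None else default_parameter_space()
    calibrated: Dict[str, LoadCase] = {}
    models = {}
    for name in config.load_cases:
        case = calibrate_load(
            default_load_case(name),
            target_risk=config.target_risk,
            age=config.age_years,
            rf=config.risk_function,
            space=space,
        )
        calibrated[name] = case
        models[name] = risk_model_for_case(case, age=config.age_years, rf=config.risk_function)
    cases = run_sensitivity_study(space, models, n_gp=config.n_gp)
    report = StudyReport(config=config, space=space, calibrated_cases=calibrated, cases=cases)
    if config.out_dir is not None:
        report.paths = _write_report(report, Path(config.out_dir))
    return report


def _config_digest(config: StudyConfig) -> str:
    payload = {
        "load_cases": list(config.load_cases),
        "n_gp": config.n_gp,
        "age_years": config.age_years,
        "target_risk": config.target_risk,
        "risk_function": [config.risk_function.b0, config.risk_function.b_age, config.risk_function.sigma],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_report(report: StudyReport, out_dir: Path) -> Dict[str, object]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, object] = {}
    summary = {
        "schema_version": 1,
        "config_digest": _config_digest(report.config),
        "n_gp": report.config.n_gp,
        "age_years": report.config.age_years,
        "target_risk": report.config.target_risk,
        "cases": {},
    }
    log_lines = [
        "thoraxvar sensitivity study",
        f"config digest: {summary['config_digest']}",
        f"parameters: {[spec.name for spec in report.space]}",
        f"N_GP: {report.config.n_gp}; age: {report.config.age_years} years; "
        f"calibration anchor NFR2+: {report.config.target_risk}",
    ]
    for name, bundle in report.cases.items():
        bundle["design"].to_csv(out_dir / f"design_{name}.csv")
        case_paths = write_index_report(bundle["result"], out_dir, name)
        case_paths["design"] = out_dir / f"design_{name}.csv"
        paths[name] = case_paths
        case = report.calibrated_cases[name]
        summary["cases"][name] = {
            "load_magnitude_nmm": case.load_magnitude,
            "delta_v_kmh": case.delta_v_kmh,
            "n_evaluations": bundle["n_evaluations"],
            "ranking": bundle["result"].ranking(),
        }
        log_lines.append(
            f"case {name}: delta-v {case.delta_v_kmh} km/h, calibrated magnitude "
            f"{case.load_magnitude:.6g} N*mm, {bundle['n_evaluations']} evaluations"
        )
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["summary"] = summary_path
    paths["log"] = log_path
    return paths


def factorial_cost(levels: int, n_params: int) -> int:
    """Evaluation count of a full factorial design: levels ** n_params.

    Exact integer arithmetic (Python ints), so no overflow for any size.
    """
    if levels < 2:
        raise ValueError("need at least 2 levels")
    if n_params < 1:
        raise ValueError("need at least 1 parameter")
    return int(levels) ** int(n_params)
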