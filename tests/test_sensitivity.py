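"""Gauss designs, M-DRM index algebra and the Monte-Carlo Sobol oracle."""

import numpy as np
import pytest

from thoraxvar.parametric_model import (
    Distribution,
    ParameterSpec,
    ParameterVector,
    default_parameter_space,
)
from thoraxvar.sensitivity import (
    DegeneracyError,
    DesignEvaluationError,
    QuadratureDesign,
    build_design,
    gauss_legendre_nodes,
    mdrm_indices,
    run_sensitivity_study,
    sobol_oracle,
    write_index_report,
)
from thoraxvar.synthetic_data import make_test_functions


class TestGaussLegendre:
    def test_single_node_midpoint_rule(self):
        nodes, weights = gauss_legendre_nodes(1, -1.0, 1.0)
        assert nodes == pytest.approx([0.0])
        assert weights == pytest.approx([2.0])

    def test_degree_nine_exactness(self):
        nodes, weights = gauss_legendre_nodes(5, -1.0, 1.0)
        assert weights @ nodes**9 == pytest.approx(0.0, abs=1e-14)
        assert weights @ nodes**8 == pytest.approx(2.0 / 9.0, abs=1e-14)
        # degree 10 is NOT integrated exactly by five points
        assert abs(weights @ nodes**10 - 2.0 / 11.0) > 1e-6

    def test_weights_sum_to_interval_length(self):
        _, weights = gauss_legendre_nodes(5, -2.0, 2.0)
        assert weights.sum() == pytest.approx(4.0)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            gauss_legendre_nodes(5, 1.0, -1.0)


class TestBuildDesign:
    def test_evaluation_budget(self, space):
        count = {"n": 0}

        def model(pv):
            count["n"] += 1
            return 1.0 + sum(pv.values.values())

        design = build_design(space, model, n_gp=5)
        assert count["n"] == 15 * 5 + 1 == design.n_evaluations == 76

    def test_constant_model_nodes_equal_h0(self, space):
        design = build_design(space, lambda pv: 3.14, n_gp=3)
        assert design.h0 == 3.14
        for name in design.parameter_names:
            assert np.all(design.evaluations[name] == 3.14)

    def test_weights_normalised_per_parameter(self, space):
        design = build_design(space, lambda pv: 1.0 + pv.get("cartilage"), n_gp=5)
        for name in design.parameter_names:
            assert design.weights[name].sum() == pytest.approx(1.0)

    def test_model_failure_wrapped(self, space):
        def bad(pv):
            if pv.get("rib_width") > 1.0:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(DesignEvaluationError) as err:
            build_design(space, bad, n_gp=5)
        assert err.value.vector is not None

    def test_design_csv_round_trip(self, space, tmp_path):
        design = build_design(space, lambda pv: 1.0 + pv.get("rib_width") ** 2, n_gp=3)
        design.to_csv(tmp_path / "design.csv")
        loaded = QuadratureDesign.from_csv(tmp_path / "design.csv")
        assert loaded.h0 == design.h0
        assert loaded.parameter_names == design.parameter_names
        for name in design.parameter_names:
            assert np.allclose(loaded.evaluations[name], design.evaluations[name])
        # indices recomputable without re-evaluating the model
        assert mdrm_indices(loaded).S == pytest.approx(mdrm_indices(design).S)

    def test_saturation_warning(self, space):
        with pytest.warns(UserWarning, match="saturation"):
            build_design(space, lambda pv: 1e-9, n_gp=2, output_bounds=(0.0, 1.0))


class TestMdrmIndices:
    def test_multiplicative_model_is_exact(self):
        tf = make_test_functions()["multiplicative"]
        design = build_design(tf.space, tf.scalar_model(), n_gp=5, cut_point=tf.cut_vector())
        res = mdrm_indices(design)
        for i, spec in enumerate(tf.space):
            assert res.S[spec.name] == pytest.approx(tf.S_analytic[i], abs=1e-10)
            assert res.S_T[spec.name] == pytest.approx(tf.S_T_analytic[i], abs=1e-10)
        # second-order indices from the same closed form
        r = 1.0 + np.array([0.6, 0.4, 0.25, 0.15]) ** 2 / 3.0
        expected_12 = (r[0] - 1.0) * (r[1] - 1.0) / (np.prod(r) - 1.0)
        assert res.S_ij[("x1", "x2")] == pytest.approx(expected_12, abs=1e-10)

    def test_single_active_parameter(self):
        specs = tuple(
            ParameterSpec(name=f"x{i}", distribution=Distribution.UNIFORM, s_range=(-1, 1))
            for i in (1, 2, 3)
        )
        design = build_design(specs, lambda pv: 2.0 + pv.get("x1") ** 2, n_gp=5)
        res = mdrm_indices(design)
        assert res.S["x1"] == pytest.approx(1.0)
        assert res.S_T["x1"] == pytest.approx(1.0)
        assert res.S["x2"] == pytest.approx(0.0, abs=1e-12)
        assert res.S_T["x3"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_model_flagged(self, space):
        res = mdrm_indices(build_design(space, lambda pv: 5.0, n_gp=3))
        assert "constant model" in res.flags
        assert all(v == 0.0 for v in res.S.values())
        assert res.V_Y == 0.0

    def test_degenerate_cut_mean_raises(self):
        specs = (ParameterSpec(name="x1", distribution=Distribution.UNIFORM, s_range=(-1, 1)),)
        design = build_design(specs, lambda pv: pv.get("x1"), n_gp=4, cut_point=ParameterVector({"x1": 0.5}))
        with pytest.raises(DegeneracyError):
            mdrm_indices(design)

    def test_invariants_on_surrogate_indices(self, space, frontal_case):
        from thoraxvar.workbench import risk_model_for_case

        res = mdrm_indices(build_design(space, risk_model_for_case(frontal_case), n_gp=5))
        s_sum = sum(res.S.values())
        assert s_sum <= 1.0 + 1e-9
        for name in res.parameter_names:
            assert -1e-9 <= res.S[name] <= res.S_T[name] + 1e-9
            assert res.tau[name] >= res.nu[name] ** 2 - 1e-12  # Jensen
        assert res.V_Y > 0


class TestSobolOracle:
    def test_additive_matches_analytic(self):
        tf = make_test_functions()["additive"]
        res = sobol_oracle(tf.f, tf.space, n_samples=16384, seed=5)
        for i, spec in enumerate(tf.space):
            tol = max(3.0 * res.se_S[spec.name], 0.01)
            assert abs(res.S[spec.name] - tf.S_analytic[i]) < tol

    def test_ishigami_matches_analytic(self):
        """The Monte-Carlo estimator itself is unbiased: it recovers the
        Ishigami closed-form indices (including the pure-interaction
        total for x3)."""
        tf = make_test_functions()["ishigami"]
        res = sobol_oracle(tf.f, tf.space, n_samples=65536, seed=11)
        for i, spec in enumerate(tf.space):
            assert abs(res.S[spec.name] - tf.S_analytic[i]) < max(3 * res.se_S[spec.name], 0.02)
            assert abs(res.S_T[spec.name] - tf.S_T_analytic[i]) < max(3 * res.se_ST[spec.name], 0.02)

    def test_constant_model(self):
        tf = make_test_functions()["constant"]
        res = sobol_oracle(tf.f, tf.space, n_samples=2048, seed=1)
        assert all(v == 0.0 for v in res.S.values())

    def test_deterministic_under_seed(self):
        tf = make_test_functions()["additive"]
        a = sobol_oracle(tf.f, tf.space, n_samples=2048, seed=9)
        b = sobol_oracle(tf.f, tf.space, n_samples=2048, seed=9)
        assert a.S == b.S and a.S_T == b.S_T

    def test_sample_floor(self):
        tf = make_test_functions()["additive"]
        with pytest.raises(ValueError):
            sobol_oracle(tf.f, tf.space, n_samples=100, seed=1)


class TestMdrmAgainstOracle:
    """Dual-route check on functions where the product form is adequate."""

    @pytest.mark.parametrize("name, ngp", [("multiplicative", 5), ("additive", 5)])
    def test_agreement(self, name, ngp):
        tf = make_test_functions()[name]
        design = build_design(tf.space, tf.scalar_model(), n_gp=ngp, cut_point=tf.cut_vector())
        mdrm = mdrm_indices(design)
        oracle = sobol_oracle(tf.f, tf.space, n_samples=65536, seed=2)
        for spec in tf.space:
            tol = max(0.05, 3.0 * oracle.se_S[spec.name])
            assert abs(mdrm.S[spec.name] - oracle.S[spec.name]) < tol
            tol_t = max(0.05, 3.0 * oracle.se_ST[spec.name])
            assert abs(mdrm.S_T[spec.name] - oracle.S_T[spec.name]) < tol_t


class TestRunStudy:
    def test_rankings_and_independence(self, space, frontal_case, near_side_case):
        from thoraxvar.workbench import risk_model_for_case

        models = {
            "frontal": risk_model_for_case(frontal_case),
            "near_side": risk_model_for_case(near_side_case),
        }
        report = run_sensitivity_study(space, models, n_gp=5)
        for name, bundle in report.items():
            res = bundle["result"]
            assert set(res.ranking()[:3]) == {"cort_thickness", "cort_material", "rib_width"}
            assert bundle["n_evaluations"] == 76
            assert len(bundle["indices"]) == 15

    def test_parameter_not_in_model_scores_zero(self, space, frontal_case):
        from thoraxvar.workbench import risk_model_for_case

        inner = risk_model_for_case(frontal_case)

        def frozen_adipose(pv):
            return inner(pv.replace("adipose", 0.0))

        report = run_sensitivity_study(space, {"frontal": frozen_adipose}, n_gp=5)
        res = report["frontal"]["result"]
        assert res.S["adipose"] == pytest.approx(0.0, abs=1e-9)
        assert res.S_T["adipose"] == pytest.approx(0.0, abs=1e-9)

    def test_index_report_files(self, space, frontal_case, tmp_path):
        from thoraxvar.workbench import risk_model_for_case

        res = mdrm_indices(build_design(space, risk_model_for_case(frontal_case), n_gp=3))
        paths = write_index_report(res, tmp_path, "frontal")
        assert all(p.exists() for p in paths.values())
        import json

        summary = json.loads(paths["summary"].read_text())
        assert summary["ranking"][0] == "cort_thickness"
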