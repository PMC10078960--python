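"""Parametric scaling expressions: printed constants, monotonicity, densities."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from thoraxvar.parametric_model import (
    CARTILAGE_SIGMA_S,
    Distribution,
    PARAMETER_NAMES,
    RAW_PRINTED_CONVENTION,
    bilinear_stress,
    default_parameter_space,
    density_for,
    load_parameter_space,
    material_table,
    save_parameter_space,
    scale_cartilage,
    scale_cortical,
    scale_geometry,
    scale_soft_tissue,
    scale_trabecular,
    spec_by_name,
)


class TestParameterSpace:
    def test_fifteen_named_specs(self, space):
        assert len(space) == 15
        assert tuple(s.name for s in space) == PARAMETER_NAMES

    def test_distribution_assignment(self, space):
        assert spec_by_name(space, "cartilage").distribution is Distribution.CARTILAGE_PERCENTILE
        for name in ("adipose", "skeletal_muscle", "intercostal_muscle"):
            assert spec_by_name(space, name).distribution is Distribution.UNIFORM
        # 6 shape modes + 3 geometry + 2 bone materials are SD-coordinates
        normals = [
            s for s in space if s.distribution is Distribution.STANDARD_NORMAL_TRUNCATED
        ]
        assert len(normals) == 11

    def test_default_range(self, space):
        assert spec_by_name(space, "cort_thickness").s_range == (-2.0, 2.0)

    def test_yaml_round_trip(self, space, tmp_path):
        path = tmp_path / "space.yaml"
        save_parameter_space(space, path)
        assert load_parameter_space(path) == space


class TestScalingExpressions:
    @pytest.mark.parametrize(
        "s, field, expected",
        [
            (0.0, "E", 14.7),
            (0.0, "sigma_Y", 100.7),
            (0.0, "P", 1.94),
            (2.0, "E", 18.7),
            (-2.0, "sigma_Y", 74.9),
        ],
    )
    def test_cortical_values(self, s, field, expected):
        assert getattr(scale_cortical(s), field) == pytest.approx(expected, abs=1e-12)

    def test_trabecular_values(self):
        nominal = scale_trabecular(0.0)
        assert (nominal.E, nominal.sigma_Y, nominal.P) == pytest.approx((25.7, 0.42, 5.66))
        assert scale_trabecular(2.0).g == pytest.approx(0.475)
        assert scale_trabecular(2.0).E == pytest.approx(47.8825)
        # the shared-term convention keeps the weakest parameter positive
        assert scale_trabecular(-2.0).P == pytest.approx(0.0075)
        assert scale_trabecular(-2.0).sigma_Y > 0

    @pytest.mark.parametrize("s, expected", [(0.0, 21.4), (2.0, 44.1), (-2.0, 7.9)])
    def test_cartilage_values(self, s, expected):
        assert scale_cartilage(s).E_eff == pytest.approx(expected, abs=1e-9)

    def test_cartilage_endpoints_match_lognormal_percentiles(self):
        """s = +/-2 hits the 5th/95th percentile of the moment-matched
        log-normal (mean 21.4 MPa, SD 12.0 MPa) within 0.5%."""
        mean, sd = 21.4, 12.0
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        ln = stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
        assert scale_cartilage(2.0).E_eff == pytest.approx(ln.ppf(0.95), rel=5e-3)
        assert scale_cartilage(-2.0).E_eff == pytest.approx(ln.ppf(0.05), rel=5e-3)

    @pytest.mark.parametrize(
        "tissue, s, field, expected",
        [
            ("adipose", 2.0, "mu", 41.0),
            ("adipose", -2.0, "mu", 29.0),
            ("muscle", 2.0, "mu", 153.0),
            ("muscle", -2.0, "mu", 63.0),
            ("muscle", 0.0, "mu", 108.0),
        ],
    )
    def test_soft_tissue_mu(self, tissue, s, field, expected):
        assert getattr(scale_soft_tissue(tissue, s), field) == pytest.approx(expected)

    def test_adipose_prony_and_poisson(self):
        hi = scale_soft_tissue("adipose", 2.0)
        assert [g for _, g in hi.prony] == pytest.approx([1.04, 2.34, 2.90])
        lo = scale_soft_tissue("adipose", -2.0)
        assert [g for _, g in lo.prony] == pytest.approx([0.56, 1.26, 1.54])
        assert lo.nu == pytest.approx(0.49978, abs=1e-5)
        assert scale_soft_tissue("adipose", 2.0).nu == pytest.approx(0.499995, abs=1e-6)
        assert scale_soft_tissue("muscle", 0.0).alpha == 13.2

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ValueError):
            scale_soft_tissue("bone", 0.0)

    def test_geometry_identity_and_endpoints(self):
        ident = scale_geometry(0.0, 0.0, 0.0)
        assert (ident.T_scale, ident.dW, ident.dH) == (1.0, 0.0, 0.0)
        assert scale_geometry(2.0, 0.0, 0.0).T_scale == pytest.approx(math.exp(0.44))
        ends = scale_geometry(0.0, 2.0, 2.0)
        assert (ends.dW, ends.dH) == pytest.approx((2.72, 3.92))

    def test_geometry_raw_convention(self):
        raw = scale_geometry(0.0, 1.0, 1.0, convention=RAW_PRINTED_CONVENTION)
        assert (raw.dW, raw.dH) == pytest.approx((2.72, 3.92))

    @pytest.mark.parametrize("fn", [scale_cortical, scale_trabecular, scale_cartilage])
    def test_out_of_range_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(2.5)

    def test_monotone_in_s(self):
        """Every scalar output is monotone non-decreasing in s on [-2, 2]."""
        grid = np.linspace(-2.0, 2.0, 41)
        series = {
            "cort_E": [scale_cortical(s).E for s in grid],
            "cort_sY": [scale_cortical(s).sigma_Y for s in grid],
            "cort_P": [scale_cortical(s).P for s in grid],
            "trab_E": [scale_trabecular(s).E for s in grid],
            "cart": [scale_cartilage(s).E_eff for s in grid],
            "adipose_mu": [scale_soft_tissue("adipose", s).mu for s in grid],
            "muscle_mu": [scale_soft_tissue("muscle", s).mu for s in grid],
            "T_scale": [scale_geometry(s, 0, 0).T_scale for s in grid],
            "dW": [scale_geometry(0, s, 0).dW for s in grid],
            "dH": [scale_geometry(0, 0, s).dH for s in grid],
        }
        for name, values in series.items():
            assert np.all(np.diff(values) > 0), f"{name} not increasing"


class TestBilinearStress:
    def test_zero_strain(self):
        assert bilinear_stress(scale_cortical(0.0), 0.0) == 0.0

    def test_continuity_at_yield(self):
        mat = scale_cortical(0.0)
        eps_y = 100.7 / 14700.0
        assert bilinear_stress(mat, eps_y) == pytest.approx(100.7, abs=1e-9)
        just_after = bilinear_stress(mat, eps_y * (1 + 1e-9))
        assert just_after == pytest.approx(100.7, rel=1e-6)

    def test_stiffer_material_dominates(self):
        grid = np.linspace(1e-5, 0.05, 200)
        hi = bilinear_stress(scale_cortical(1.0), grid)
        lo = bilinear_stress(scale_cortical(-1.0), grid)
        assert np.all(hi >= lo)
        assert np.all(np.diff(bilinear_stress(scale_cortical(0.0), grid)) > 0)

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            bilinear_stress(scale_cortical(0.0), -0.01)

    def test_trabecular_units_consistent(self):
        mat = scale_trabecular(0.0)
        eps_y = mat.sigma_Y / mat.E
        assert bilinear_stress(mat, eps_y) == pytest.approx(mat.sigma_Y)


class TestDensities:
    def test_uniform_density_value(self, space):
        assert density_for(1.5, spec_by_name(space, "adipose")) == pytest.approx(0.25)

    def test_truncated_normal_at_zero(self, space):
        spec = spec_by_name(space, "cort_material")
        expected = stats.norm.pdf(0.0) / (stats.norm.cdf(2) - stats.norm.cdf(-2))
        assert density_for(0.0, spec) == pytest.approx(expected)
        assert density_for(0.0, spec) == pytest.approx(0.4178, abs=5e-4)

    def test_cartilage_percentile_tail_mass(self, space):
        """The cartilage s-density descends from P(s <= -2) = 0.05 before
        truncation (5th-percentile correspondence)."""
        assert stats.norm.cdf(-2.0, scale=CARTILAGE_SIGMA_S) == pytest.approx(0.05)

    @pytest.mark.parametrize("name", PARAMETER_NAMES)
    def test_all_densities_normalise(self, space, name):
        spec = spec_by_name(space, name)
        total, _ = integrate.quad(lambda s: density_for(s, spec), *spec.s_range)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_density_outside_range_rejected(self, space):
        with pytest.raises(ValueError):
            density_for(3.0, spec_by_name(space, "adipose"))


def test_material_table_is_tidy():
    frame = material_table((0.0, 2.0))
    assert set(frame.columns) == {"parameter", "s", "field", "value", "unit"}
    cell = frame.query("parameter == 'cort_material' and s == 0 and field == 'E'")
    assert cell["value"].iloc[0] == 14.7 and cell["unit"].iloc[0] == "GPa"
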