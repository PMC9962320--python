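"""Model catalog: covariate formulas, random-effect conventions, serialization."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtxpk import (
    CovariateRecord,
    build_model_catalog,
    catalog_from_yaml,
    catalog_to_yaml,
    compute_bsa,
    compute_egfr,
    get_model,
    individual_params,
    omega_matrix,
    residual_variance,
    typical_params,
)
from mtxpk.models import CovariateError, MissingCovariateError, iov_variances


class TestCovariateDerivation:
    @pytest.mark.parametrize(
        "height,scr,expected",
        [(100.0, 0.413, 100.0), (113.0, 0.31, 150.54516129032257)],
    )
    def test_schwartz_egfr(self, height, scr, expected):
        assert compute_egfr(height, scr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("height,scr", [(113.0, 0.0), (0.0, 0.31), (-5.0, 0.3)])
    def test_egfr_rejects_non_positive_inputs(self, height, scr):
        with pytest.raises(CovariateError):
            compute_egfr(height, scr)

    @pytest.mark.parametrize(
        "height,weight,formula,expected",
        [
            (3600.0, 1.0, "mosteller", 1.0),
            (113.0, 19.0, "mosteller", 0.7722621892135396),
            # DuBois value frozen from independent hand arithmetic
            (120.0, 26.1, "dubois", 0.9243680853694668),
        ],
    )
    def test_bsa_formulas(self, height, weight, formula, expected):
        assert compute_bsa(height, weight, formula) == pytest.approx(expected, rel=1e-12)

    def test_bsa_unknown_formula_is_configuration_error(self):
        with pytest.raises(ValueError, match="unknown BSA formula"):
            compute_bsa(120.0, 20.0, "boyd")

    def test_record_derives_unit_twins_and_bsa_and_egfr(self):
        rec = CovariateRecord(patient_id="p", height=113.0, weight=19.0, scr_mgdl=0.31)
        assert rec.scr_umol == pytest.approx(0.31 * 88.42, rel=1e-12)
        assert rec.bsa == pytest.approx(0.7722621892135396, rel=1e-12)
        assert rec.egfr == pytest.approx(150.54516129032257, rel=1e-12)

    def test_record_rejects_inconsistent_creatinine_units(self):
        with pytest.raises(CovariateError, match="inconsistent creatinine"):
            CovariateRecord(patient_id="p", scr_mgdl=0.31, scr_umol=30.0)

    def test_record_rejects_non_positive_covariates(self):
        with pytest.raises(CovariateError):
            CovariateRecord(patient_id="p", weight=-3.0)


class TestCatalog:
    def test_six_models_with_expected_structures(self, catalog):
        assert len(catalog) == 6
        by_name = {m.name: m for m in catalog}
        assert by_name["gao"].n_compartments == 3
        assert all(m.n_compartments == 2 for n, m in by_name.items() if n != "gao")
        assert by_name["aumente"].parameterization == "micro-constant"
        assert by_name["jonsson"].iiv["CL"] == 109.0

    def test_jonsson_assumed_proportional_error(self, catalog):
        jon = get_model("jonsson", catalog)
        assert jon.ruv_proportional == pytest.approx(0.30)
        assert jon.ruv_additive == 0.0

    def test_yaml_round_trip_preserves_every_model(self, catalog):
        text = catalog_to_yaml(catalog)
        restored = catalog_from_yaml(io.StringIO(text))
        assert restored == catalog

    def test_unknown_model_lookup_lists_available(self, catalog):
        with pytest.raises(KeyError, match="available"):
            get_model("nosuchmodel", catalog)


class TestTypicalParams:
    def test_gao_reference_clearance(self, catalog):
        cov = CovariateRecord(patient_id="p", weight=19.0, scr_umol=26.0)
        tp = typical_params(get_model("gao", catalog), cov)
        assert tp.values["CL"] == pytest.approx(6.9, rel=1e-12)

    def test_jonsson_reference_clearance_and_volume(self, jonsson):
        cov = CovariateRecord(patient_id="p", weight=19.0)
        tp = typical_params(jonsson, cov)
        assert tp.values["CL"] == pytest.approx(3.515, rel=1e-12)
        assert tp.values["V1"] == pytest.approx(24.13, rel=1e-12)

    def test_medellin_unit_bsa_clearance(self, medellin):
        cov = CovariateRecord(patient_id="p", bsa=1.0, weight=10.0)
        tp = typical_params(medellin, cov)
        assert tp.values["CL"] == pytest.approx(6.5, rel=1e-12)
        assert tp.values["V1"] == pytest.approx(3.6, rel=1e-12)

    def test_hui_reference_covariates_recover_printed_clearance(self, catalog):
        hui = get_model("hui", catalog)
        cov = CovariateRecord(
            patient_id="p", bsa=0.735, egfr=192.0 * 1.73 / 0.735, age=5.29
        )
        assert typical_params(hui, cov).values["CL"] == pytest.approx(7.73, rel=1e-12)

    def test_hui_literal_parenthesization_differs(self, reference_child):
        absolute = get_model("hui", build_model_catalog(hui_renal="absolute"))
        literal = get_model("hui", build_model_catalog(hui_renal="literal"))
        cl_abs = typical_params(absolute, reference_child).values["CL"]
        cl_lit = typical_params(literal, reference_child).values["CL"]
        assert cl_abs != pytest.approx(cl_lit)

    @pytest.mark.parametrize(
        "age,branch_factor",
        [(9.99, 0.287 * 19.0**0.876), (10.0, 0.149 * 19.0), (12.0, 0.149 * 19.0)],
    )
    def test_aumente_age_branch_boundary(self, catalog, age, branch_factor):
        """Age exactly 10 years falls in the '>10 years' arm."""
        cov = CovariateRecord(patient_id="p", age=age, weight=19.0)
        tp = typical_params(get_model("aumente", catalog), cov)
        assert tp.values["CL"] == pytest.approx(branch_factor, rel=1e-12)

    def test_zhang_gender_lowers_female_clearance(self, catalog, reference_child):
        zhang = get_model("zhang", catalog)
        import dataclasses

        girl = dataclasses.replace(reference_child, sex="F", bsa=None, egfr=None)
        cl_boy = typical_params(zhang, reference_child).values["CL"]
        cl_girl = typical_params(zhang, girl).values["CL"]
        assert cl_girl < cl_boy

    def test_missing_covariate_without_default_names_model_and_covariate(self, catalog):
        zhang = get_model("zhang", catalog)
        cov = CovariateRecord(patient_id="p", sex="M", age=5.0, bsa=0.8)  # no OH
        with pytest.raises(MissingCovariateError) as err:
            typical_params(zhang, cov)
        assert err.value.model_name == "zhang"
        assert err.value.covariate == "oh"

    def test_development_defaults_fill_missing_covariates(self, catalog):
        # Gao published medians stand in when the record lacks the covariate
        gao = get_model("gao", catalog)
        tp = typical_params(gao, CovariateRecord(patient_id="p"))
        assert tp.values["CL"] > 0

    @pytest.mark.parametrize("name", ["aumente", "gao", "hui", "medellin", "zhang", "jonsson"])
    def test_monotone_in_body_size(self, catalog, name, reference_child):
        """Clearance never decreases when the body-size covariate grows."""
        import dataclasses

        model = get_model(name, catalog)
        small = reference_child
        big = dataclasses.replace(
            reference_child, weight=30.0, height=140.0, bsa=None, egfr=None
        )
        cl_small = typical_params(model, small).values["CL"]
        cl_big = typical_params(model, big).values["CL"]
        assert cl_big >= cl_small


class TestIndividualParams:
    def test_zero_etas_equal_typical(self, medellin, reference_child):
        tp = typical_params(medellin, reference_child)
        ip = individual_params(medellin, reference_child, np.zeros(3))
        assert ip.values == pytest.approx(tp.values)

    def test_eta_scales_lognormally(self, jonsson, reference_child):
        etas = np.array([math.log(2.0), 0.0, 0.0, 0.0])
        ip = individual_params(jonsson, reference_child, etas)
        assert ip.values["CL"] == pytest.approx(7.03, rel=1e-12)
        assert ip.values["V1"] == pytest.approx(24.13, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(eta=st.floats(min_value=-2.0, max_value=2.0))
    def test_log_symmetry(self, eta, jonsson, reference_child):
        """individual(eta) * individual(-eta) = typical^2 per parameter."""
        tp = typical_params(jonsson, reference_child)
        up = individual_params(jonsson, reference_child, np.array([eta, 0, 0, 0]))
        dn = individual_params(jonsson, reference_child, np.array([-eta, 0, 0, 0]))
        assert up.values["CL"] * dn.values["CL"] == pytest.approx(
            tp.values["CL"] ** 2, rel=1e-9
        )

    def test_eta_dimension_mismatch_raises(self, medellin, reference_child):
        with pytest.raises(ValueError, match="expected 3 etas"):
            individual_params(medellin, reference_child, np.zeros(2))

    def test_occasion_isolation_for_iov(self, catalog, reference_child):
        """A kappa on occasion 2 leaves occasion-1 clearance untouched."""
        hui = get_model("hui", catalog)
        kap = np.array([[0.0], [0.1]])
        occ1 = individual_params(hui, reference_child, np.zeros(2), kappas=kap, occasion=0)
        occ2 = individual_params(hui, reference_child, np.zeros(2), kappas=kap, occasion=1)
        base = typical_params(hui, reference_child)
        assert occ1.values["CL"] == pytest.approx(base.values["CL"], rel=1e-12)
        assert occ2.values["CL"] == pytest.approx(base.values["CL"] * math.exp(0.1), rel=1e-12)


class TestVariabilityAndError:
    def test_jonsson_omega_diagonal(self, jonsson):
        om = omega_matrix(jonsson)
        assert om == pytest.approx(np.diag([1.09**2, 0.26**2, 0.22**2, 0.44**2]))

    def test_single_iiv_gives_1x1_matrix(self, catalog):
        gao = get_model("gao", catalog)
        assert omega_matrix(gao).shape == (2, 2)
        one_eta = get_model("medellin", catalog)
        assert omega_matrix(one_eta).shape == (3, 3)

    def test_hui_iov_variance(self, catalog):
        hui = get_model("hui", catalog)
        assert iov_variances(hui) == pytest.approx([0.149**2])

    def test_lognormal_convention_selectable(self, jonsson):
        om = omega_matrix(jonsson, convention="lognormal")
        assert om[0, 0] == pytest.approx(math.log(1 + 1.09**2))

    @pytest.mark.parametrize(
        "model_name,ipred,expected",
        [
            ("aumente", 1.0, 0.162**2 + 0.0035**2),
            ("gao", 0.0, 0.0),  # pure proportional model vanishes at zero
            ("jonsson", 2.0, (0.30 * 2.0) ** 2),
        ],
    )
    def test_residual_variance(self, catalog, model_name, ipred, expected):
        model = get_model(model_name, catalog)
        assert residual_variance(model, ipred) == pytest.approx(expected, rel=1e-12)
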