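"""Property values, empirical-CDF calibration and pass/warning/fail labels."""

from fractions import Fraction

import numpy as np
import pytest

from implicitl2o.certificates import (CalibrationTable, LabelPolicy,
                                      PropertySpec, assign_label, calibrate,
                                      certify, empirical_cdf, is_trustworthy,
                                      property_box_distance,
                                      property_iterate_residual, property_l1,
                                      property_rel_error, property_sparsity,
                                      property_total_variation)
from implicitl2o.linops import make_matrix_map
from implicitl2o.solvers import iterate_to_fixed_point


class TestPropertyValues:
    def test_sparsity_counts(self):
        assert property_sparsity(np.array([1.0, 0.0, 0.0, 2.0]), 0.0) == 2
        assert property_sparsity(np.zeros(5)) == 0
        assert property_sparsity(np.array([1e-9, 1.0]), 1e-6) == 1

    def test_rel_error(self):
        I = make_matrix_map(np.eye(2))
        assert property_rel_error(I, np.array([3.0, 4.0]), np.array([3.0, 4.0])) == 0.0
        assert property_rel_error(I, np.zeros(2), np.array([3.0, 4.0])) == 1.0
        assert property_rel_error(I, np.array([3.0, 0.0]), np.array([3.0, 4.0])) == \
            pytest.approx(0.8)

    def test_rel_error_zero_data_rejected(self):
        with pytest.raises(ValueError):
            property_rel_error(make_matrix_map(np.eye(2)), np.ones(2), np.zeros(2))

    def test_total_variation(self):
        assert property_total_variation(np.full((4, 4), 0.7)) == 0.0
        assert property_total_variation(np.array([[0.0, 1.0]])) == 1.0
        assert property_total_variation(np.array([[0.0, 1.0], [0.0, 1.0]])) == 2.0

    def test_box_distance(self):
        assert property_box_distance(np.array([0.5, 0.2])) == 0.0
        assert property_box_distance(np.array([1.5])) == pytest.approx(0.5)
        assert property_box_distance(np.array([-3.0, 2.0])) == pytest.approx(np.sqrt(10))

    def test_iterate_residual_geometric(self):
        st = iterate_to_fixed_point(lambda x: x / 2, np.array([1.0]), 1e-12, 3)
        assert property_iterate_residual(st) == pytest.approx(0.125)
        st0 = iterate_to_fixed_point(lambda x: x, np.array([2.0]), 1e-9, 10)
        assert property_iterate_residual(st0) == 0.0

    def test_l1(self):
        assert property_l1(np.array([1.0, -2.0, 0.5])) == pytest.approx(3.5)


class TestEmpiricalCdf:
    def test_inclusive_counting(self):
        t = CalibrationTable("p", np.array([1.0, 2.0, 3.0, 4.0]))
        assert empirical_cdf(2.5, t) == 0.5
        assert empirical_cdf(0.5, t) == 0.0
        assert empirical_cdf(4.0, t) == 1.0   # ties counted inclusively
        assert empirical_cdf(9.0, t) == 1.0

    def test_monotone_nondecreasing_sweep(self, rng):
        t = CalibrationTable("p", rng.exponential(size=200))
        xs = np.sort(rng.uniform(0, 8, size=1000))
        vals = [empirical_cdf(x, t) for x in xs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_strict_variant_differs_only_at_ties(self):
        t = CalibrationTable("p", np.array([0.0, 0.0, 0.0]))
        assert empirical_cdf(0.0, t) == 1.0
        assert t.cdf_lower(0.0) == 0.0


class TestLabels:
    def test_paper_policy_examples(self):
        policy = LabelPolicy("0.95", "0", "0.05")
        assert assign_label(0.5, policy) == "pass"
        assert assign_label(0.96, policy) == "fail"   # warning band is empty
        assert assign_label(0.95, policy) == "fail"

    def test_warning_band(self):
        policy = LabelPolicy("0.8", "0.15", "0.05")
        assert assign_label(0.85, policy) == "warning"
        assert assign_label(0.79, policy) == "pass"
        assert assign_label(0.95, policy) == "fail"

    def test_partition_of_unit_interval(self):
        policy = LabelPolicy("0.8", "0.15", "0.05")
        for c in np.linspace(0, 1, 101):
            assert assign_label(float(c), policy) in {"pass", "warning", "fail"}

    def test_invalid_cdf_rejected(self):
        with pytest.raises(ValueError):
            assign_label(1.5, LabelPolicy("0.95", "0"))

    def test_policy_probabilities_exact_rationals(self):
        p = LabelPolicy("0.95", p_fail="0.05")
        assert p.p_pass + p.p_warn + p.p_fail == 1
        assert p.p_pass == Fraction(19, 20) and p.p_warn == 0

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            LabelPolicy("0.7", "0.5", "0.5")


class TestCalibrateAndCertify:
    def test_single_record_table(self):
        prop = PropertySpec("v", lambda rec: rec["v"])
        t = calibrate(prop, [{"v": 2.0}])
        assert t.N == 1
        assert empirical_cdf(2.0, t) == 1.0 and empirical_cdf(1.9, t) == 0.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            calibrate(PropertySpec("v", lambda rec: 1.0), [])

    def test_uniform_concentration(self, rng):
        prop = PropertySpec("v", lambda rec: rec["v"])
        t = calibrate(prop, [{"v": v} for v in rng.uniform(0, 1, 100)])
        assert 0.35 <= empirical_cdf(0.5, t) <= 0.65

    def test_recalibration_identical(self, rng):
        prop = PropertySpec("v", lambda rec: rec["v"])
        recs = [{"v": v} for v in rng.exponential(size=50)]
        np.testing.assert_array_equal(calibrate(prop, recs).samples,
                                      calibrate(prop, recs).samples)

    def test_certify_median_passes_and_max_fails(self, rng):
        props = [PropertySpec("a", lambda rec: rec["a"]),
                 PropertySpec("b", lambda rec: rec["b"])]
        recs = [{"a": v, "b": w} for v, w in
                zip(rng.uniform(1, 2, 200), rng.uniform(1, 2, 200))]
        tables = {p.name: calibrate(p, recs) for p in props}
        policy = LabelPolicy("0.95", "0", "0.05")
        median_rec = {"a": float(np.median(tables["a"].samples)),
                      "b": float(np.median(tables["b"].samples))}
        certs = certify(median_rec, props, tables, policy)
        assert [c.name for c in certs] == ["a", "b"]
        assert all(c.label == "pass" for c in certs)
        assert is_trustworthy(certs)
        extreme = {"a": 10.0, "b": median_rec["b"]}
        certs = certify(extreme, props, tables, policy)
        assert certs[0].label == "fail" and certs[0].cdf == 1.0
        assert not is_trustworthy(certs)

    def test_missing_table_named(self):
        with pytest.raises(KeyError, match="mystery"):
            certify({}, [PropertySpec("mystery", lambda rec: 0.0)], {},
                    LabelPolicy("0.95", "0"))

    def test_empty_property_list(self):
        assert certify({}, [], {}, LabelPolicy("0.95", "0")) == []

    def test_pass_rate_matches_policy_for_continuous_draws(self, rng):
        # fresh i.i.d. draws from the calibration distribution pass at rate
        # ~p_pass (binomial fluctuation band)
        prop = PropertySpec("v", lambda rec: rec["v"])
        policy = LabelPolicy("0.9", "0", "0.1")
        table = calibrate(prop, [{"v": v} for v in rng.exponential(size=1000)])
        n = 1000
        labels = [assign_label(table.cdf_lower(v), policy)
                  for v in rng.exponential(size=n)]
        rate = np.mean([lab == "pass" for lab in labels])
        band = 3 * np.sqrt(0.9 * 0.1 / n)
        assert abs(rate - 0.9) <= band + 1e-3

    def test_constant_property_all_pass(self):
        # a property that holds by construction (identically zero) passes
        prop = PropertySpec("zero", lambda rec: 0.0)
        table = calibrate(prop, [{} for _ in range(50)])
        certs = certify({}, [prop], {"zero": table}, LabelPolicy("0.95", "0"))
        assert certs[0].label == "pass"
        assert certs[0].cdf == 1.0 and certs[0].cdf_lower == 0.0
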