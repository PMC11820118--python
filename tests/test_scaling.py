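"""Scaling-law ansaetze, through-origin fits, and published predictions."""

import math

import numpy as np
import pytest

from pldscale import (
    Ansatz,
    MutationSpec,
    PUBLISHED_LAWS,
    ScalingLaw,
    VariantObservation,
    ansatz_x,
    build_table1,
    cumulative_prediction,
    fit_scaling_constant,
    lookup_law,
    predict_delta_tc,
    select_ansatz,
)
from pldscale.scaling import normalize_pair, reverse_pair
from pldscale.synthetic_data import FamilyTruth, synth_variant_family


def obs(pair, n, L, y, i=0):
    return VariantObservation(f"v{i}", pair, n, L, y)


class TestAnsatzX:
    def test_three_forms(self):
        assert ansatz_x(4, 100, Ansatz.COUNT) == 4.0
        assert ansatz_x(4, 100, Ansatz.FRACTION) == pytest.approx(0.04)
        assert ansatz_x(4, 100, Ansatz.SQRT) == pytest.approx(0.4)

    def test_zero_mutations(self):
        for a in Ansatz:
            assert ansatz_x(0, 137, a) == 0.0

    def test_forms_coincide_only_at_unit_length(self):
        assert ansatz_x(3, 1, Ansatz.FRACTION) == ansatz_x(3, 1, Ansatz.SQRT) == 3.0
        assert ansatz_x(3, 4, Ansatz.FRACTION) != ansatz_x(3, 4, Ansatz.SQRT)


class TestPairLabels:
    def test_normalization(self):
        assert normalize_pair("Y/F→X") == "F/Y->X"
        assert normalize_pair("R->K") == "R->K"

    def test_reverse(self):
        assert reverse_pair("Y->F") == "F->Y"


class TestFit:
    def test_exact_line(self):
        data = [obs("Y->F", n, 100, -2.0 * n, i) for i, n in enumerate([1, 2, 3])]
        law = fit_scaling_constant(data, Ansatz.COUNT)
        assert law.S == pytest.approx(-2.0)
        assert law.r_squared == pytest.approx(1.0)

    def test_all_zero_response(self):
        data = [obs("Y->F", n, 100, 0.0, i) for i, n in enumerate([1, 2, 3])]
        law = fit_scaling_constant(data, Ansatz.COUNT)
        assert law.S == 0.0

    def test_mixed_pairs_rejected(self):
        data = [obs("Y->F", 1, 100, -0.4), obs("R->K", 1, 100, -13.0, 1)]
        with pytest.raises(ValueError, match="mixed"):
            fit_scaling_constant(data, Ansatz.COUNT)

    def test_multi_type_refused(self):
        bad = VariantObservation("v", "Y->F", 1, 100, -0.4, multi_type=True)
        with pytest.raises(ValueError, match="multi-type"):
            fit_scaling_constant([bad], Ansatz.COUNT)

    def test_single_observation_slope_defined_error_undefined(self):
        law = fit_scaling_constant([obs("Y->F", 2, 100, -0.8)], Ansatz.COUNT)
        assert law.S == pytest.approx(-0.4)
        assert law.S_err is None

    def test_synthetic_family_recovered_within_two_standard_errors(self):
        truth = FamilyTruth(pair="R->K", ansatz=Ansatz.FRACTION, S_truth=-1300.0,
                            noise_sd=2.0, seed=13)
        law = fit_scaling_constant(synth_variant_family(truth), Ansatz.FRACTION)
        assert abs(law.S - truth.S_truth) < 2.0 * law.S_err

    def test_matches_independent_least_squares(self):
        """Cross-check the closed-form through-origin slope and its standard
        error against a no-intercept statsmodels OLS fit."""
        import statsmodels.api as sm

        truth = FamilyTruth(pair="R->K", ansatz=Ansatz.FRACTION, noise_sd=2.0, seed=3)
        data = synth_variant_family(truth)
        law = fit_scaling_constant(data, Ansatz.FRACTION)
        x = np.array([ansatz_x(o.count, o.length, Ansatz.FRACTION) for o in data])
        y = np.array([o.delta_tc for o in data])
        res = sm.OLS(y, x).fit()
        assert law.S == pytest.approx(res.params[0], rel=1e-10)
        assert law.S_err == pytest.approx(res.bse[0], rel=1e-10)


class TestSelectAnsatz:
    def test_sqrt_generated_family_selected(self):
        truth = FamilyTruth(pair="F/Y->X", ansatz=Ansatz.SQRT, S_truth=-56.0,
                            lengths=(100, 200, 300), counts=(2, 5, 8, 11),
                            n_obs=24, noise_sd=0.5, seed=4)
        sel = select_ansatz(synth_variant_family(truth))
        assert sel.best == Ansatz.SQRT
        assert not sel.indistinguishable

    def test_constant_length_indistinguishable(self):
        data = [obs("Y->F", n, 137, -0.4 * n, i) for i, n in enumerate([1, 3, 5])]
        sel = select_ansatz(data)
        assert sel.best is None and sel.indistinguishable

    def test_reversed_family_flips_sign_keeps_r_squared(self):
        truth = FamilyTruth(pair="R->K", ansatz=Ansatz.FRACTION, noise_sd=1.0, seed=5)
        data = synth_variant_family(truth)
        flipped = [
            VariantObservation(o.variant_id, "K->R", o.count, o.length, -o.delta_tc)
            for o in data
        ]
        law = fit_scaling_constant(data, Ansatz.FRACTION)
        law_rev = fit_scaling_constant(flipped, Ansatz.FRACTION)
        assert law_rev.S == pytest.approx(-law.S)
        assert law_rev.r_squared == pytest.approx(law.r_squared)


class TestPublishedPredictions:
    def test_arg_to_lys_single_mutation_L200(self):
        pred = predict_delta_tc(None, 200, pair="R->K", count=1)
        assert pred.value == pytest.approx(-6.5)
        assert pred.error == pytest.approx(0.5)

    def test_arg_deletion_single_mutation_L100(self):
        pred = predict_delta_tc(None, 100, pair="R->X", count=1)
        assert pred.value == pytest.approx(-6.4)
        assert pred.error == pytest.approx(0.5)

    def test_zero_mutations_zero_shift(self):
        pred = predict_delta_tc(None, 100, pair="R->K", count=0)
        assert pred.value == 0.0 and pred.error == 0.0

    def test_reversed_direction_flips_sign(self):
        fwd = predict_delta_tc(None, 200, pair="Y->F", count=1)
        rev = predict_delta_tc(None, 200, pair="F->Y", count=1)
        assert rev.value == pytest.approx(-fwd.value)

    def test_bound_spec_interface(self):
        spec = MutationSpec(source="R", target="K", count=3)
        pred = predict_delta_tc(spec, 200)
        assert pred.value == pytest.approx(-1300 * 3 / 200)

    def test_mismatched_law_rejected(self):
        law = lookup_law("R->K")
        with pytest.raises(ValueError, match="law is for pair"):
            predict_delta_tc(None, 200, law=law, pair="N->Q", count=1)

    def test_class_without_constant_refused(self):
        with pytest.raises(ValueError, match="no.*constant|refusing"):
            predict_delta_tc(None, 200, pair="G->S", count=1)

    def test_multi_type_spec_refused(self):
        spec = MutationSpec(source="Y/R", target="F/K", count=2, multi_type=True)
        with pytest.raises(ValueError, match="multi-type"):
            predict_delta_tc(spec, 200)


class TestCumulative:
    def test_single_spec_reduces_to_predict(self):
        spec = MutationSpec(source="R", target="K", count=1)
        combined = cumulative_prediction([spec], 200)
        single = predict_delta_tc(spec, 200)
        assert combined.value == pytest.approx(single.value)
        assert combined.error == pytest.approx(single.error)

    def test_two_class_sum(self):
        specs = [MutationSpec(source="Y", target="F", count=2),
                 MutationSpec(source="R", target="K", count=1)]
        combined = cumulative_prediction(specs, 200)
        assert combined.value == pytest.approx(-0.8 + -6.5)
        assert combined.error == pytest.approx(math.hypot(2 * 0.04, 0.5))

    def test_empty_sum(self):
        combined = cumulative_prediction([], 200)
        assert combined.value == 0.0 and combined.error == 0.0


class TestTable1:
    def test_length_free_columns_constant(self):
        grid = build_table1()
        for pair in ("Y->F", "F/Y->W", "S->T", "G->T", "A->S"):
            vals = grid[grid["pair"] == pair]["delta_tc_K"].to_numpy()
            assert np.allclose(vals, vals[0])

    def test_quoted_cells(self):
        grid = build_table1().set_index(["pair", "L"])
        assert grid.loc[("R->K", 100), "delta_tc_K"] == pytest.approx(-13.0)
        assert grid.loc[("R->K", 100), "err_K"] == pytest.approx(1.0)
        assert grid.loc[("N->Q", 300), "delta_tc_K"] == pytest.approx(0.17, abs=0.005)
        assert grid.loc[("Y->F", 300), "delta_tc_K"] == pytest.approx(-0.4)

    def test_errors_scale_with_ansatz_variable(self):
        grid = build_table1().set_index(["pair", "L"])
        law = PUBLISHED_LAWS["R->X"]
        for L in (100, 200, 300):
            assert grid.loc[("R->X", L), "err_K"] == pytest.approx(law.S_err / L)


class TestParameterRecoveryStudy:
    @pytest.mark.parametrize("ansatz", list(Ansatz))
    def test_bias_below_standard_error_and_coverage(self, ansatz):
        """Across seeds, the through-origin estimator of S is unbiased to
        within its standard error and ~95% of 2-sigma intervals cover the
        generating constant."""
        s_truth = {Ansatz.COUNT: -0.4, Ansatz.FRACTION: -1300.0, Ansatz.SQRT: -56.0}[ansatz]
        estimates, covered = [], 0
        n_seeds = 100
        for seed in range(n_seeds):
            truth = FamilyTruth(pair="R->K", ansatz=ansatz, S_truth=s_truth,
                                lengths=(100, 150, 200, 250, 300),
                                noise_sd=2.0, seed=seed)
            law = fit_scaling_constant(synth_variant_family(truth), ansatz)
            estimates.append(law.S)
            if abs(law.S - s_truth) < 2 * law.S_err:
                covered += 1
        bias = np.mean(estimates) - s_truth
        spread = np.std(estimates, ddof=1) / np.sqrt(n_seeds)
        assert abs(bias) < 4 * spread  # consistent with zero at Monte-Carlo error
        assert covered >= 90  # ~95% nominal, binomial slack
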