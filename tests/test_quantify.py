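"""Reference ratios, gradient fits, %CV and MRM quantifier selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from csfpre.io import SampleMeta
from csfpre.quantify import (
    MrmMeasurement,
    RatioTable,
    Transition,
    filter_quantifiable,
    fit_gradient,
    fit_gradient_table,
    fold_change,
    percent_cv,
    ratio_to_reference,
    rollup_peptides,
    select_quantifier_transition,
)

REF = SampleMeta("ref", "reference")


class TestRatioToReference:
    def test_reference_against_itself_gives_unit_ratios(self):
        meta = {"ref": REF, "s": SampleMeta("s", "rcg_point", rcg_point=1)}
        m = make_matrix({"ref": [4.0, 2.0], "s": [4.0, 2.0]}, meta)
        rt = ratio_to_reference(m)
        assert np.allclose(rt.ratios["rcg_1"], 1.0)

    def test_simple_division(self):
        meta = {"ref": REF, "s": SampleMeta("s", "rcg_point", rcg_point=2)}
        m = make_matrix({"ref": [4.0], "s": [8.0]}, meta)
        assert ratio_to_reference(m).ratios.iloc[0, 0] == pytest.approx(2.0)

    def test_duplicate_channels_averaged_before_ratio(self):
        # channels 3 and 5 for the same point, reference 4 -> mean 4, ratio 1
        meta = {
            "ref": REF,
            "a": SampleMeta("a", "rcg_point", rcg_point=1),
            "b": SampleMeta("b", "rcg_point", rcg_point=1),
        }
        m = make_matrix({"ref": [4.0], "a": [3.0], "b": [5.0]}, meta)
        rt = ratio_to_reference(m)
        assert list(rt.ratios.columns) == ["rcg_1"]
        assert rt.ratios.at["P0", "rcg_1"] == pytest.approx(1.0)

    def test_missingness_propagates_and_zero_reference_blanks(self):
        meta = {"ref": REF, "s": SampleMeta("s", "rcg_point", rcg_point=1)}
        m = make_matrix({"ref": [4.0, 0.0, np.nan], "s": [np.nan, 2.0, 2.0]}, meta)
        rt = ratio_to_reference(m)
        assert rt.ratios["rcg_1"].isna().all()

    def test_entirely_missing_reference_is_an_error(self):
        meta = {"ref": REF, "s": SampleMeta("s", "rcg_point", rcg_point=1)}
        m = make_matrix({"ref": [np.nan], "s": [2.0]}, meta)
        with pytest.raises(ValueError, match="entirely missing"):
            ratio_to_reference(m)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,symmetric,expected",
        [
            (3.0, 3.0, True, 1.0),
            (0.675, 0.414, True, 1.63),  # total protein, lumbar vs ventricular
            (2.0, 8.0, True, 4.0),
            (8.0, 2.0, True, 4.0),
            (2.0, 8.0, False, 0.25),
        ],
    )
    def test_values(self, a, b, symmetric, expected):
        assert round(fold_change(a, b, symmetric=symmetric), 2) == expected

    def test_non_positive_input_yields_missing(self):
        assert math.isnan(fold_change(0.0, 2.0))
        assert math.isnan(fold_change(2.0, float("nan")))


class TestFitGradient:
    def test_perfectly_linear_profile_has_unit_r_squared(self):
        fit = fit_gradient(np.linspace(1.0, 1.6, 7))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_defined_as_zero_r_squared(self):
        fit = fit_gradient([2.5] * 7)
        assert fit.r_squared == 0.0 and fit.evaluable

    def test_decreasing_profile_slope_and_end_point_fold_change(self):
        fit = fit_gradient([1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 1.0])
        assert fit.slope == pytest.approx(-0.1, abs=1e-12)
        assert fit.fc_1_7 == pytest.approx(1.6, abs=1e-12)
        assert fit.fc_2_7 == pytest.approx(1.5, abs=1e-12)
        assert fit.increasing_toward_lumbar is True

    def test_fewer_than_three_points_not_evaluable(self):
        fit = fit_gradient([1.0, np.nan, np.nan, np.nan, np.nan, np.nan, 1.6])
        assert not fit.evaluable and fit.n_points == 2

    def test_fitted_endpoint_option_uses_the_line(self):
        y = [1.6, 1.45, 1.45, 1.3, 1.2, 1.1, 1.0]
        observed = fit_gradient(y)
        fitted = fit_gradient(y, fitted_endpoints=True)
        assert observed.fc_1_7 == pytest.approx(1.6)
        assert fitted.fc_1_7 != observed.fc_1_7

    def test_r_squared_matches_brute_force_least_squares_oracle(self):
        # oracle: design-matrix least squares + the R^2 definition, written
        # independently of the closed-form moment implementation
        rng = np.random.default_rng(2024)
        for _ in range(300):
            y = rng.lognormal(0.0, 0.5, 7)
            x = np.arange(1.0, 8.0)
            beta, *_ = np.linalg.lstsq(np.column_stack([x, np.ones(7)]), y, rcond=None)
            resid = y - (beta[0] * x + beta[1])
            ss_tot = np.sum((y - y.mean()) ** 2)
            oracle = 1.0 - np.sum(resid**2) / ss_tot
            assert fit_gradient(y).r_squared == pytest.approx(oracle, abs=1e-10)

    def test_table_fit_marks_sparse_proteins_not_evaluable(self):
        ratios = pd.DataFrame(
            {f"rcg_{k}": [1.0 + 0.1 * k, np.nan] for k in range(1, 8)},
            index=pd.Index(["full", "sparse"], name="accession"),
        )
        ratios.loc["sparse", ["rcg_1", "rcg_7"]] = [1.0, 1.6]
        fits = fit_gradient_table(RatioTable(ratios, reference="reference"))
        assert fits.at["full", "evaluable"] and fits.at["full", "r_squared"] == pytest.approx(1.0)
        assert not fits.at["sparse", "evaluable"]


class TestPercentCv:
    def test_identical_values_have_zero_cv(self):
        assert percent_cv([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # sd(1,1,1,1,2) = 0.4472, mean 1.2 -> 37.3%
        assert percent_cv([1, 1, 1, 1, 2]) == pytest.approx(37.2678, abs=1e-3)

    def test_single_value_is_missing(self):
        assert math.isnan(percent_cv([5.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 1e4), min_size=2, max_size=10),
        st.floats(0.01, 1e3),
    )
    def test_scale_invariance(self, values, k):
        cv = percent_cv(values)
        assert percent_cv([k * v for v in values]) == pytest.approx(cv, rel=1e-9, abs=1e-9)


class TestMrm:
    def _measurement(self):
        return MrmMeasurement(
            "ELVISLIVESK",
            (
                Transition("y4", 120.0, 100.0),
                Transition("y5", 150.0, 200.0),
                Transition("y6", 40.0, 50.0),
            ),
        )

    def test_most_intense_sis_transition_chosen(self):
        m = select_quantifier_transition(self._measurement())
        assert m.chosen_transition == "y5"
        assert m.ratio == pytest.approx(150.0 / 200.0)

    def test_flagged_top_transition_falls_back_to_next(self):
        m = select_quantifier_transition(self._measurement(), {"y5": True})
        assert m.chosen_transition == "y4"
        assert m.ratio == pytest.approx(1.2)

    def test_all_flagged_excludes_peptide(self, caplog):
        m = select_quantifier_transition(
            self._measurement(), {"y4": True, "y5": True, "y6": True}
        )
        assert m is None

    def test_fewer_than_three_transitions_rejected(self):
        with pytest.raises(ValueError, match="3 transitions"):
            MrmMeasurement("PEPTIDEK", (Transition("y1", 1, 1), Transition("y2", 1, 1)))


class TestRollup:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ([1.4], 1.4),
            ([1.0, 1.2, 5.0], 1.2),  # median robust to one outlier
            ([1.0, 1.4], 1.2),
        ],
    )
    def test_median_rollup(self, ratios, expected):
        out = rollup_peptides({"ACC": ratios})
        assert out.at["ACC", "ratio"] == pytest.approx(expected)
        assert out.at["ACC", "n_peptides"] == len(ratios)

    def test_protein_without_peptides_rejected(self):
        with pytest.raises(ValueError):
            rollup_peptides({"ACC": [float("nan")]})


class TestFilterQuantifiable:
    def _matrix(self, counts):
        meta = {f"P{i}_CSF": SampleMeta(f"P{i}_CSF", "patient_fluid",
                                        patient_id=f"P{i}", fluid="CSF")
                for i in range(1, 6)}
        values = {sid: [1.0] * len(counts) for sid in meta}
        pc = pd.DataFrame(counts, index=[f"A{i}" for i in range(len(counts))],
                          columns=list(meta))
        return make_matrix(values, meta, accessions=list(pc.index), peptide_counts=pc)

    def test_two_peptides_in_two_patients_retained(self):
        m = self._matrix([[2, 2, 0, 0, 0]])
        kept, report = filter_quantifiable(m, 2, 2)
        assert kept.accessions == ["A0"] and report.empty

    def test_single_peptide_everywhere_removed_with_reason(self):
        m = self._matrix([[1, 1, 1, 1, 1]])
        kept, report = filter_quantifiable(m, 2, 2)
        assert kept.accessions == []
        assert "unique peptides" in report.iloc[0]["reason"]

    def test_zero_thresholds_are_identity(self):
        m = self._matrix([[0, 0, 0, 0, 0], [1, 0, 0, 0, 0]])
        kept, report = filter_quantifiable(m, 0, 0)
        assert kept.accessions == ["A0", "A1"] and report.empty
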