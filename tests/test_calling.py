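"""Skew-adjusted boundaries, per-female calls, genic aggregation, subtypes."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from xcical.calling import (
    StatusBoundaries,
    aggregate_genic,
    call_gene,
    female_boundaries,
    par1_range_classes,
    variable_subtype,
)
from xcical.grouping import AutosomalThresholds, Group1Reference
from xcical.model import CallLevel, GenicStatus, VariableSubtype, expected_ai

_THR = AutosomalThresholds(0.10, 0.20, 0.36, "LCL1")


def _profile(group, skew=np.nan, slope=np.nan, intercept=np.nan):
    return pd.Series({"sample": "F1", "sample_set": "LCL1", "group": group,
                      "skew": skew, "slope": slope, "intercept": intercept})


class TestFemaleBoundaries:
    def test_group1_subject_boundary_from_worked_example(self):
        b = female_boundaries(_profile("1", skew=0.8891), _THR)
        assert round(b.e3_s, 4) == 0.3184
        assert b.e1_e2 == _THR.q90 and b.e2_e3 == _THR.q95

    def test_group2_identity_regression_matches_group1(self):
        ref = Group1Reference(pd.Series(dtype=float), skew=0.8891)
        b2 = female_boundaries(_profile("2", skew=0.8891, slope=1.0, intercept=0.0),
                               _THR, reference=ref)
        b1 = female_boundaries(_profile("1", skew=0.8891), _THR)
        assert (b2.e1_e2, b2.e2_e3, b2.e3_s) == pytest.approx(
            (b1.e1_e2, b1.e2_e3, b1.e3_s))

    def test_group2_linear_map(self):
        ref = Group1Reference(pd.Series(dtype=float), skew=0.95)
        b = female_boundaries(_profile("2", skew=0.7, slope=0.5, intercept=0.0),
                              _THR, reference=ref)
        assert b.e1_e2 == pytest.approx(0.05)
        assert b.e2_e3 == pytest.approx(0.10)
        assert b.e3_s == pytest.approx(0.5 * expected_ai(0.95, 0.10))

    def test_group_r_has_no_boundaries(self):
        with pytest.raises(ValueError, match="group"):
            female_boundaries(_profile("R"), _THR)


class TestCallGene:
    B = StatusBoundaries("F1", 0.10, 0.20, expected_ai(0.8891, 0.10))

    def test_high_ai_is_subject_with_clamped_xi(self):
        status, xi = call_gene(0.45, self.B, 0.8891)
        assert status is CallLevel.S and xi == 0.0

    def test_balanced_ai_is_e1_with_full_xi(self):
        status, xi = call_gene(0.0, self.B, 0.8891)
        assert status is CallLevel.E1 and xi == pytest.approx(1.0)

    def test_boundary_tie_breaks_to_subject(self):
        status, _ = call_gene(self.B.e3_s, self.B, 0.8891)
        assert status is CallLevel.S

    def test_graded_escape_levels(self):
        assert call_gene(0.05, self.B, 0.8891)[0] is CallLevel.E1
        assert call_gene(0.15, self.B, 0.8891)[0] is CallLevel.E2
        assert call_gene(0.25, self.B, 0.8891)[0] is CallLevel.E3


def _calls(status_list, xi=0.1):
    return pd.DataFrame({
        "sample": [f"S{i}" for i in range(len(status_list))],
        "sample_set": "LCL1",
        "gene": "G1",
        "n_probes": 2,
        "ai": 0.2,
        "xi": xi,
        "status": status_list,
    })


class TestAggregateGenic:
    def test_seven_of_nine_is_escape(self):
        genic = aggregate_genic(_calls(["E1"] * 7 + ["S"] * 2))
        assert genic.iloc[0]["status"] == GenicStatus.ESCAPE.value
        assert genic.iloc[0]["frac_escaping"] == pytest.approx(7 / 9)

    def test_none_escaping_is_subject(self):
        genic = aggregate_genic(_calls(["S"] * 10))
        assert genic.iloc[0]["status"] == GenicStatus.SUBJECT.value
        assert genic.iloc[0]["frac_escaping"] == 0.0

    def test_half_escaping_is_variable(self):
        genic = aggregate_genic(_calls(["E2"] * 5 + ["S"] * 5))
        assert genic.iloc[0]["status"] == GenicStatus.VARIABLE_ESCAPE.value
        assert genic.iloc[0]["subtype"] != ""

    def test_exact_rational_boundaries(self):
        # 2/9 escaping is still subject; 7/9 already escape
        assert aggregate_genic(_calls(["E1"] * 2 + ["S"] * 7)).iloc[0]["status"] \
            == GenicStatus.SUBJECT.value
        assert aggregate_genic(
            _calls(["E1"] * 7 + ["S"] * 2),
            subject_max=Fraction(2, 9), escape_min=Fraction(7, 9),
        ).iloc[0]["status"] == GenicStatus.ESCAPE.value

    def test_min_females_skips_gene(self):
        genic = aggregate_genic(_calls(["E1"]), min_females=2)
        assert genic.empty

    def test_partition_is_exhaustive(self, default_result):
        genic = default_result.genic
        assert set(genic["status"]) <= {s.value for s in GenicStatus}
        variable = genic["status"] == GenicStatus.VARIABLE_ESCAPE.value
        assert (genic.loc[variable, "subtype"] != "").all()
        assert (genic.loc[~variable, "subtype"] == "").all()


class TestVariableSubtype:
    @pytest.mark.parametrize(
        "statuses, subtype",
        [
            (["E1", "E1", "S", "S"], VariableSubtype.BIMODAL),
            (["S", "E3", "S", "E3"], VariableSubtype.BORDERLINE),
            (["S", "E2", "E3", "E1"], VariableSubtype.HETEROGENEOUS),
            (["E1", "E1", "S", "E2", "E3", "E3", "S", "E2"],
             VariableSubtype.HETEROGENEOUS),  # 4/8 in {E1, S}, E2 present
        ],
    )
    def test_examples(self, statuses, subtype):
        assert variable_subtype(statuses) is subtype

    def test_bimodal_requires_both_extremes(self):
        # all S with one E3 fails bimodal (no E1) and is borderline
        assert variable_subtype(["S", "S", "S", "E3"]) is VariableSubtype.BORDERLINE


def _genic(rows):
    return pd.DataFrame(rows, columns=["gene", "status", "mean_xi"])


class TestPar1RangeClasses:
    PAR1 = ["P1", "P2"]

    def test_escape_in_and_out_of_range(self):
        genic = _genic([
            ("P1", "escape", 0.49), ("P2", "escape", 0.73),
            ("E1", "escape", 0.60), ("E2", "escape", 0.30),
        ])
        out = par1_range_classes(genic, self.PAR1).set_index("gene")
        assert out.loc["E1", "expression_class"] == "escape_in_PAR1_range"
        assert out.loc["E2", "expression_class"] == "escape_outside_PAR1_range"
        assert out.loc["P1", "expression_class"] == "escape_in_PAR1_range"

    def test_subject_split_inclusive_at_five_percent(self):
        genic = _genic([("G1", "subject", 0.049), ("G2", "subject", 0.05)])
        out = par1_range_classes(genic, self.PAR1).set_index("gene")
        assert out.loc["G1", "expression_class"] == "subject_lt5"
        assert out.loc["G2", "expression_class"] == "subject_ge5"

    def test_variable_genes_unclassed(self):
        genic = _genic([("P1", "escape", 0.6), ("V1", "variable_escape", 0.2)])
        out = par1_range_classes(genic, self.PAR1).set_index("gene")
        assert out.loc["V1", "expression_class"] == ""

    def test_no_par1_collapses_with_warning(self, caplog):
        genic = _genic([("E1", "escape", 0.6), ("G1", "subject", 0.01)])
        out = par1_range_classes(genic, []).set_index("gene")
        assert out.loc["E1", "expression_class"] == "escape_unclassed"
        assert out.loc["G1", "expression_class"] == "subject_lt5"


class TestGenicRecovery:
    def test_status_accuracy_on_cohort(self, default_cohort, default_result):
        probes, truth = default_cohort
        tg = truth.genes.reset_index(drop=True)
        merged = default_result.genic.merge(tg[["gene", "true_status"]], on="gene")
        informative = merged[merged["n_females"] >= 5]
        assert len(informative) >= 100
        accuracy = (informative["status"] == informative["true_status"]).mean()
        assert accuracy >= 0.90

    def test_recovered_xi_tracks_truth_monotonically(self):
        # regenerating the cohort with a higher true %Xi (all else fixed)
        # never lowers the recovered mean %Xi beyond the noise tolerance
        from xcical._util import ai_of_fraction, informative_x_rows
        from xcical.model import xi_from_ai
        from xcical.simulate import CohortConfig, simulate_cohort

        recovered = []
        for xi in (0.0, 0.2, 0.4):
            cfg = CohortConfig(seed=21, n_x_genes=40, n_females_per_set=10,
                               n_subject_training=0, n_escape_training=0,
                               n_autosomal_probes=800, fixed_xi=xi,
                               n_population_specific=0, n_cell_line_specific=0,
                               n_imprinted=0, skew_values=tuple([0.95] * 30))
            probes, _ = simulate_cohort(cfg)
            rows = informative_x_rows(probes)
            ai = ai_of_fraction(rows["frac_expr"])
            recovered.append(float(np.mean(xi_from_ai(np.minimum(ai, 0.5), 0.95))))
        assert recovered[1] >= recovered[0] - 0.02
        assert recovered[2] >= recovered[1] - 0.02
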