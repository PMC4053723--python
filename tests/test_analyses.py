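"""Adjacency clustering, cross-set decision tree, group-R screen, ChIP classes."""

import numpy as np
import pandas as pd
import pytest

from xcical.analyses import (
    adjacency_chi_square,
    adjacency_counts,
    chip_class_compare,
    cross_set_classify,
    group_r_allelic,
    permutation_expected,
)


def _genic(statuses, genes=None):
    genes = genes or [f"G{i}" for i in range(len(statuses))]
    return pd.DataFrame({"gene": genes, "status": statuses})


def _positions(genes):
    return pd.Series({g: 1000 * (i + 1) for i, g in enumerate(genes)})


class TestAdjacencyCounts:
    def test_uniform_run(self):
        genic = _genic(["subject"] * 3)
        counts = adjacency_counts(genic, _positions(genic["gene"]))
        assert counts == {("subject", "subject"): 2}

    def test_unordered_pairs(self):
        genic = _genic(["escape", "subject", "escape"])
        counts = adjacency_counts(genic, _positions(genic["gene"]))
        assert counts == {("escape", "subject"): 2}

    def test_hand_enumerated_twelve_genes(self):
        seq = ["subject", "subject", "escape", "escape", "variable_escape",
               "subject", "subject", "subject", "escape", "variable_escape",
               "variable_escape", "subject"]
        genic = _genic(seq)
        counts = adjacency_counts(genic, _positions(genic["gene"]))
        assert counts == {
            ("subject", "subject"): 3,
            ("escape", "subject"): 2,
            ("escape", "escape"): 1,
            ("escape", "variable_escape"): 2,
            ("subject", "variable_escape"): 2,
            ("variable_escape", "variable_escape"): 1,
        }
        assert sum(counts.values()) == len(seq) - 1

    def test_par1_exclusion(self):
        genic = _genic(["escape", "escape", "subject"])
        counts = adjacency_counts(genic, _positions(genic["gene"]),
                                  par1_genes={"G0"})
        assert counts == {("escape", "subject"): 1}

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            adjacency_counts(_genic(["subject"]), _positions(["G0"]))


class TestAdjacencyChiSquare:
    def test_equal_observed_expected_is_null(self):
        obs = {("subject", "subject"): 10, ("escape", "subject"): 5}
        res = adjacency_chi_square(obs, {k: float(v) for k, v in obs.items()})
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_expected_pair_excluded(self):
        obs = {("subject", "subject"): 10, ("escape", "escape"): 2}
        with pytest.warns(UserWarning, match="zero expected"):
            res = adjacency_chi_square(obs, {("subject", "subject"): 10.0})
        assert len(res.table) == 1


class TestPermutationExpected:
    def test_matches_closed_form_two_statuses(self):
        # 4 A and 6 B over 10 positions: expected adjacent pair counts under
        # exchangeable labels are (n-1) * [hypergeometric pair probabilities]
        genic = _genic(["A"] * 4 + ["B"] * 6)
        pos = _positions(genic["gene"])
        expected, _ = permutation_expected(genic, pos, n_permutations=4000,
                                           seed=5, exclude_par1=False)
        assert expected[("A", "A")] == pytest.approx(9 * 12 / 90, abs=0.15)
        assert expected[("B", "B")] == pytest.approx(9 * 30 / 90, abs=0.2)
        assert expected[("A", "B")] == pytest.approx(9 * 48 / 90, abs=0.2)

    def test_single_status_is_its_own_null(self):
        genic = _genic(["subject"] * 6)
        expected, p = permutation_expected(genic, _positions(genic["gene"]),
                                           n_permutations=200, seed=1,
                                           exclude_par1=False)
        assert expected[("subject", "subject")] == 5.0
        assert p == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        genic = _genic(["A", "B", "A", "B", "B", "A", "B", "B"])
        pos = _positions(genic["gene"])
        e1, p1 = permutation_expected(genic, pos, 300, seed=9, exclude_par1=False)
        e2, p2 = permutation_expected(genic, pos, 300, seed=9, exclude_par1=False)
        assert e1 == e2 and p1 == p2

    def test_clustered_arrangement_detected(self):
        genic = _genic(["A"] * 10 + ["B"] * 10)
        _, p = permutation_expected(genic, _positions(genic["gene"]),
                                    n_permutations=500, seed=2,
                                    exclude_par1=False)
        assert p < 0.05


SETS = ("LCL1", "LCL2")
OTHER = "FIB"


class TestCrossSetClassify:
    @pytest.mark.parametrize(
        "a, b, c, category",
        [
            ("escape", "escape", "escape", "consistent_escape"),
            ("subject", "subject", None, "consistent_subject"),
            ("variable_escape", "variable_escape", "variable_escape",
             "consistent_variable"),
            ("escape", "subject", None, "population_specific"),
            ("escape", "subject", "escape", "population_specific"),
            ("subject", "subject", "escape", "cell_line_specific"),
            ("escape", "subject", "variable_escape", "population_and_cell_line"),
            ("escape", None, "subject", "inconsistent"),
            ("escape", None, None, "not_classifiable"),
            (None, None, "subject", "not_classifiable"),
        ],
    )
    def test_decision_tree(self, a, b, c, category):
        statuses = {SETS[0]: a, SETS[1]: b, OTHER: c}
        assert cross_set_classify(statuses, SETS, OTHER) == category

    def test_symmetric_in_same_cell_type_sets(self):
        for a in ("escape", "subject", "variable_escape", None):
            for b in ("escape", "subject", None):
                for c in ("escape", "subject", "variable_escape", None):
                    fwd = cross_set_classify({SETS[0]: a, SETS[1]: b, OTHER: c},
                                             SETS, OTHER)
                    rev = cross_set_classify({SETS[0]: b, SETS[1]: a, OTHER: c},
                                             SETS, OTHER)
                    assert fwd == rev


def _r_gene_ai(records):
    """records: (sample, sample_set, gene, ai)."""
    return pd.DataFrame(
        [(s, ss, g, 2, a) for s, ss, g, a in records],
        columns=["sample", "sample_set", "gene", "n_probes", "ai"],
    )


class TestGroupRAllelic:
    Q995 = {"LCL1": 0.33}

    def test_balanced_gene_called_biallelic(self):
        gene_ai = _r_gene_ai([(f"S{i}", "LCL1", "G1", 0.02) for i in range(6)])
        calls, genic = group_r_allelic(gene_ai, [f"S{i}" for i in range(6)], self.Q995)
        assert not calls["mono_allelic"].any()
        assert genic.iloc[0]["category"] == "bi"

    def test_imprinted_like_gene_called_mono(self):
        gene_ai = _r_gene_ai([(f"S{i}", "LCL1", "G1", 0.48) for i in range(6)])
        _, genic = group_r_allelic(gene_ai, [f"S{i}" for i in range(6)], self.Q995)
        assert genic.iloc[0]["category"] == "mono"

    def test_one_of_seven_mono_is_biallelic(self):
        ais = [0.48] + [0.02] * 6
        gene_ai = _r_gene_ai([(f"S{i}", "LCL1", "G1", a) for i, a in enumerate(ais)])
        _, genic = group_r_allelic(gene_ai, [f"S{i}" for i in range(7)], self.Q995)
        assert genic.iloc[0]["category"] == "bi"       # 6/7 bi-allelic >= 7/9

    def test_mixed_gene_is_variable_allelic(self):
        ais = [0.48] * 3 + [0.02] * 3
        gene_ai = _r_gene_ai([(f"S{i}", "LCL1", "G1", a) for i, a in enumerate(ais)])
        _, genic = group_r_allelic(gene_ai, [f"S{i}" for i in range(6)], self.Q995)
        assert genic.iloc[0]["category"] == "variable_allelic"


def _chip_table(class_ai, n_per_class=60, sd=0.03, seed=0):
    """One mark; one gene per class with promoter+body probes."""
    rng = np.random.default_rng(seed)
    rows, ann_rows = [], []
    for k, (cls, mean) in enumerate(sorted(class_ai.items())):
        gene = f"G_{cls}"
        start, end = 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 50_000
        ann_rows.append(("chrX", start, end, gene, 0, "+", 0))
        for j in range(n_per_class):
            ai = float(np.clip(rng.normal(mean, sd), 0, 0.49)) if sd else mean
            pos = start + 2000 + j if j >= 2 else start + j  # 2 promoter probes
            rows.append((f"c{gene}{j}", gene, "chrX", pos, "S0", "F", "LCL1",
                         1, 5000.0, 0.5 + ai, 0.5, "chip:H3K4me3"))
    from xcical.io import PROBE_COLUMNS

    chip = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    ann = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "gene", "score", "strand", "par1"]
    )
    ann["tss"] = ann["start"]
    ann["tes"] = ann["end"]
    classes = pd.Series({f"G_{cls}": cls for cls in class_ai})
    return chip, ann, classes


class TestChipClassCompare:
    def test_strong_effect_recovers_ordering_and_significance(self):
        means = {"subject_lt5": 0.30, "subject_ge5": 0.22,
                 "escape_outside_PAR1_range": 0.14, "escape_in_PAR1_range": 0.06}
        chip, ann, classes = _chip_table(means, n_per_class=80, sd=0.03, seed=4)
        summaries = chip_class_compare(chip, ann, classes)
        body = next(s for s in summaries if s.region == "gene_body")
        got = body.class_stats.set_index("expression_class")["mean_ai"]
        order = sorted(means, key=means.get)
        assert list(got.loc[order].sort_values().index) == order
        assert body.pairwise["significant"].all()

    def test_single_class_no_tests(self):
        chip, ann, classes = _chip_table({"subject_lt5": 0.3}, n_per_class=20)
        summaries = chip_class_compare(chip, ann, classes)
        for s in summaries:
            assert s.pairwise.empty
            assert len(s.class_stats) == 1

    def test_sparse_class_excluded_and_reported(self):
        chip, ann, classes = _chip_table(
            {"subject_lt5": 0.3, "subject_ge5": 0.2}, n_per_class=40
        )
        chip = pd.concat([chip, chip.iloc[[0]].assign(
            probe_id="lonely", gene="G_escape_in_PAR1_range")], ignore_index=True)
        ann = pd.concat([ann, ann.iloc[[0]].assign(
            gene="G_escape_in_PAR1_range")], ignore_index=True)
        classes = pd.concat([classes, pd.Series(
            {"G_escape_in_PAR1_range": "escape_in_PAR1_range"})])
        summaries = chip_class_compare(chip, ann, classes)
        prom = next(s for s in summaries if s.region == "promoter")
        assert "escape_in_PAR1_range" in prom.excluded_classes
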