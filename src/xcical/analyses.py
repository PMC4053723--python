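"""Chromosome-scale downstream analyses.

* adjacency clustering: do neighbouring genes share an XCI status more often
  than chance?  Observed counts of unordered status pairs over consecutive
  classified genes (PAR1 excluded) are compared with expected counts --
  either supplied directly or derived by permuting the status labels over
  the gene positions -- via per-pair chi-square components and standardized
  residuals;
* cross-sample-set comparison: a decision tree over per-set genic statuses
  separating consistent, population-specific, cell-line-specific and
  inconsistent XCI;
* group-R allelic screen: in females with effectively random XCI every
  X-linked gene should look bi-allelic, so mono-allelic genes (mean AI above
  the set's 99.5th autosomal percentile) are imprinting candidates;
* histone ChIP-AI comparison: allelic imbalance of chromatin marks at
  promoters (TSS +/- 1 kb) and gene bodies (TSS to TES) across the four
  Xi-expression classes, with pairwise Welch t-tests and Holm correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import ai_of_fraction
from .model import GenicStatus

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


def _pair_key(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


def adjacency_counts(genic: pd.DataFrame, positions: pd.Series,
                     par1_genes=(), exclude_par1: bool = True) -> dict[PairKey, int]:
    """Observed unordered status-pair counts over consecutive classified genes.

    ``genic`` needs columns gene and status; ``positions`` maps gene id to a
    chromosome coordinate.  Position ties break by gene id.
    """
    sub = genic
    if exclude_par1:
        sub = sub[~sub["gene"].isin(set(par1_genes))]
    sub = sub.assign(_pos=sub["gene"].map(positions))
    if sub["_pos"].isna().any():
        missing = sub.loc[sub["_pos"].isna(), "gene"].iloc[0]
        raise ValueError(f"gene {missing!r} has no position")
    sub = sub.sort_values(["_pos", "gene"], kind="mergesort")
    statuses = sub["status"].tolist()
    if len(statuses) < 2:
        raise ValueError("need at least two classified genes for adjacency analysis")
    counts: dict[PairKey, int] = {}
    for a, b in zip(statuses, statuses[1:]):
        key = _pair_key(a, b)
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class AdjacencyResult:
    """Per-pair chi-square decomposition of the adjacency counts.

    ``table`` has one row per status pair: observed, expected, the component
    (observed - expected)^2 / expected and the standardized residual
    (observed - expected) / expected^(1/2).
    """

    table: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    empirical_p: float | None = None


def adjacency_chi_square(observed: dict[PairKey, int],
                         expected: dict[PairKey, float],
                         df: int | None = None) -> AdjacencyResult:
    """Chi-square decomposition of observed vs expected adjacency counts.

    Pairs with zero expected count are excluded with a warning.  The total
    statistic is referred to a chi-square distribution with ``df`` degrees
    of freedom (default: number of included pairs minus one).
    """
    keys = sorted(set(observed) | set(expected))
    rows = []
    for key in keys:
        o = float(observed.get(key, 0))
        e = float(expected.get(key, 0.0))
        if e <= 0:
            warnings.warn(f"pair {key} has zero expected count; excluded")
            continue
        rows.append((f"{key[0]}|{key[1]}", o, e, (o - e) ** 2 / e, (o - e) / np.sqrt(e)))
    table = pd.DataFrame(
        rows, columns=["pair", "observed", "expected", "component", "std_residual"]
    )
    statistic = float(table["component"].sum())
    dof = df if df is not None else max(len(table) - 1, 1)
    p = float(stats.chi2.sf(statistic, dof))
    return AdjacencyResult(table=table, statistic=statistic, df=dof, p_value=p)


def permutation_expected(genic: pd.DataFrame, positions: pd.Series,
                         n_permutations: int = 1000, seed: int = 0,
                         par1_genes=(), exclude_par1: bool = True,
                         ) -> tuple[dict[PairKey, float], float]:
    """Expected pair counts and an empirical clustering p by label permutation.

    Status labels are shuffled over the (fixed) gene positions; expected
    counts are the mean pair counts over permutations, and the empirical p
    compares the observed total chi-square statistic against the permuted
    distribution (add-one correction).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    sub = genic
    if exclude_par1:
        sub = sub[~sub["gene"].isin(set(par1_genes))]
    sub = sub.assign(_pos=sub["gene"].map(positions))
    sub = sub.sort_values(["_pos", "gene"], kind="mergesort")
    statuses = np.asarray(sub["status"].tolist())
    n = len(statuses)
    if n < 2:
        raise ValueError("need at least two classified genes")

    rng = np.random.default_rng(seed)
    levels = sorted(set(statuses))
    keys = [_pair_key(a, b) for a, b in combinations(levels, 2)]
    keys += [(lvl, lvl) for lvl in levels]
    keys = sorted(set(keys))
    index = {k: i for i, k in enumerate(keys)}

    def count_vector(labels) -> np.ndarray:
        vec = np.zeros(len(keys))
        for a, b in zip(labels, labels[1:]):
            vec[index[_pair_key(a, b)]] += 1
        return vec

    obs_vec = count_vector(statuses)
    perm = np.empty((n_permutations, len(keys)))
    for i in range(n_permutations):
        perm[i] = count_vector(statuses[rng.permutation(n)])
    expected_vec = perm.mean(axis=0)

    def chi_stat(vec: np.ndarray) -> float:
        mask = expected_vec > 0
        return float(np.sum((vec[mask] - expected_vec[mask]) ** 2 / expected_vec[mask]))

    stat_obs = chi_stat(obs_vec)
    stat_perm = np.array([chi_stat(perm[i]) for i in range(n_permutations)])
    p_emp = float((1 + np.sum(stat_perm >= stat_obs)) / (n_permutations + 1))
    expected = {k: float(expected_vec[i]) for k, i in index.items() if expected_vec[i] > 0}
    return expected, p_emp


CROSS_SET_CATEGORIES = (
    "consistent_subject", "consistent_variable", "consistent_escape",
    "population_specific", "cell_line_specific", "population_and_cell_line",
    "inconsistent", "not_classifiable",
)


def cross_set_classify(statuses: dict[str, str | None],
                       same_cell_type_sets: tuple[str, str],
                       other_cell_type_set: str) -> str:
    """Decision tree over per-set genic statuses.

    ``statuses`` maps sample-set label to a genic status or None when the
    set has too few informative females.  The two same-cell-type sets are
    compared first (a disagreement is population-specific unless the third
    set shows that both the population and cell-type axes differ); then the
    other cell type is brought in (a consistent LCL pair differing from it
    is cell-line-specific).  Fewer than two informative sets cannot be
    classified.
    """
    set_a, set_b = same_cell_type_sets
    a = statuses.get(set_a)
    b = statuses.get(set_b)
    c = statuses.get(other_cell_type_set)
    informative = [s for s in (a, b, c) if s is not None]
    if len(informative) < 2:
        return "not_classifiable"
    if len(set(informative)) == 1:
        status = GenicStatus(informative[0])
        return {
            GenicStatus.SUBJECT: "consistent_subject",
            GenicStatus.VARIABLE_ESCAPE: "consistent_variable",
            GenicStatus.ESCAPE: "consistent_escape",
        }[status]
    if a is not None and b is not None and a != b:
        if c is not None and c != a and c != b:
            return "population_and_cell_line"
        return "population_specific"
    if a is not None and b is not None and a == b:
        # c must be informative and different (otherwise consistent above)
        return "cell_line_specific"
    # only one LCL set informative and it disagrees with the other cell type
    return "inconsistent"


def cross_set_table(calls: pd.DataFrame, min_females: int = 5,
                    same_cell_type_sets: tuple[str, str] = ("LCL1", "LCL2"),
                    other_cell_type_set: str = "FIB",
                    subject_max: Fraction = Fraction(2, 9),
                    escape_min: Fraction = Fraction(7, 9)) -> pd.DataFrame:
    """Per-set genic statuses and their cross-set category for every gene."""
    from .calling import aggregate_genic

    per_set: dict[str, pd.DataFrame] = {}
    for sset, grp in calls.groupby("sample_set", sort=True):
        genic = aggregate_genic(grp, min_females=min_females,
                                subject_max=subject_max, escape_min=escape_min)
        per_set[sset] = genic.set_index("gene")

    sets = sorted(set(per_set) | set(same_cell_type_sets) | {other_cell_type_set})
    genes = sorted({g for table in per_set.values() for g in table.index})
    rows = []
    for gene in genes:
        statuses = {
            sset: (per_set[sset].loc[gene, "status"]
                   if sset in per_set and gene in per_set[sset].index else None)
            for sset in sets
        }
        category = cross_set_classify(statuses, same_cell_type_sets, other_cell_type_set)
        rows.append([gene] + [statuses[s] or "uninformative" for s in sets] + [category])
    return pd.DataFrame(rows, columns=["gene"] + [f"status_{s}" for s in sets] + ["category"])


def group_r_allelic(gene_ai: pd.DataFrame, group_r_samples,
                    q995_by_set: dict[str, float],
                    subject_max: Fraction = Fraction(2, 9),
                    escape_min: Fraction = Fraction(7, 9),
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mono- vs bi-allelic expression in group-R (random-XCI) females.

    A gene is mono-allelic in a female when its mean AI exceeds the sample
    set's own 99.5th autosomal percentile (no cross-set rescaling).  The
    genic category applies the 2/9 - 7/9 fraction rule to the *bi-allelic*
    fraction: mostly mono-allelic genes (bi fraction <= 2/9) are imprinting
    candidates.  Returns (per-female calls, genic table).
    """
    keep = gene_ai[gene_ai["sample"].isin(set(group_r_samples))].copy()
    if keep.empty:
        return (
            pd.DataFrame(columns=["sample", "sample_set", "gene", "ai", "mono_allelic"]),
            pd.DataFrame(columns=["gene", "n_females", "frac_biallelic", "category"]),
        )
    keep["mono_allelic"] = keep["ai"] > keep["sample_set"].map(q995_by_set).astype(float)
    calls = keep[["sample", "sample_set", "gene", "ai", "mono_allelic"]].reset_index(drop=True)

    rows = []
    for gene, grp in calls.groupby("gene", sort=True):
        n = len(grp)
        bi = int((~grp["mono_allelic"]).sum())
        frac_bi = Fraction(bi, n)
        if frac_bi <= subject_max:
            category = "mono"
        elif frac_bi >= escape_min:
            category = "bi"
        else:
            category = "variable_allelic"
        rows.append((gene, n, float(frac_bi), category))
    genic = pd.DataFrame(rows, columns=["gene", "n_females", "frac_biallelic", "category"])
    return calls, genic


@dataclass
class ChipClassSummary:
    """Per mark x region class summary plus corrected pairwise tests."""

    mark: str
    region: str
    class_stats: pd.DataFrame          # expression_class, n, mean_ai, sem
    pairwise: pd.DataFrame             # class_a, class_b, t, p_raw, p_corrected, significant
    excluded_classes: list[str] = field(default_factory=list)


def assign_chip_regions(chip: pd.DataFrame, annotation: pd.DataFrame,
                        promoter_window: int = 1000) -> pd.DataFrame:
    """Assign each ChIP probe row to promoter and/or gene-body of its gene.

    The promoter is [TSS - w, TSS + w) on the strand-resolved TSS; the gene
    body is the annotated interval [start, end).  A probe near the TSS can
    contribute to both regions, so rows may be duplicated with different
    region labels.
    """
    ann = annotation.reset_index(drop="gene" in annotation.columns)
    merged = chip.merge(
        ann[["gene", "start", "end", "tss"]], on="gene", how="inner"
    )
    out = []
    promoter = merged[
        (merged["pos"] >= merged["tss"] - promoter_window)
        & (merged["pos"] < merged["tss"] + promoter_window)
    ].assign(region="promoter")
    body = merged[
        (merged["pos"] >= merged["start"]) & (merged["pos"] < merged["end"])
    ].assign(region="gene_body")
    out = pd.concat([promoter, body], ignore_index=True)
    return out.drop(columns=["start", "end", "tss"])


def chip_class_compare(chip: pd.DataFrame, annotation: pd.DataFrame,
                       expression_classes: pd.Series,
                       promoter_window: int = 1000,
                       correction: str = "holm",
                       alpha: float = 0.05) -> list[ChipClassSummary]:
    """Compare mean |ChIP AI| across expression classes per mark and region.

    ``chip`` holds informative rows with channel ``chip:<mark>``;
    ``expression_classes`` maps gene id to its class.  Within each mark x
    region family, all pairwise two-tailed Welch t-tests are corrected with
    ``correction`` (Holm by default).  Classes with fewer than two probes
    are excluded from testing and reported.
    """
    chip = chip[chip["informative"] == 1].copy()
    chip["mark"] = chip["channel"].str.replace("chip:", "", regex=False)
    chip["ai"] = ai_of_fraction(chip["frac_expr"])
    chip["expression_class"] = chip["gene"].map(expression_classes)
    chip = chip.dropna(subset=["expression_class"])
    chip = chip[chip["expression_class"] != ""]
    regions = assign_chip_regions(chip, annotation, promoter_window)

    summaries: list[ChipClassSummary] = []
    for (mark, region), grp in regions.groupby(["mark", "region"], sort=True):
        stats_rows = []
        groups: dict[str, np.ndarray] = {}
        excluded = []
        for cls, sub in grp.groupby("expression_class", sort=True):
            vals = sub["ai"].to_numpy(dtype=float)
            stats_rows.append((cls, len(vals), float(vals.mean()),
                               float(vals.std(ddof=1) / np.sqrt(len(vals)))
                               if len(vals) > 1 else float("nan")))
            if len(vals) >= 2:
                groups[cls] = vals
            else:
                excluded.append(cls)
        class_stats = pd.DataFrame(
            stats_rows, columns=["expression_class", "n", "mean_ai", "sem"]
        )
        pairs = list(combinations(sorted(groups), 2))
        pair_rows = []
        if pairs:
            raw = []
            for a, b in pairs:
                t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                raw.append((a, b, float(t), float(p)))
            reject, p_corr, _, _ = multipletests(
                [r[3] for r in raw], alpha=alpha, method=correction
            )
            for (a, b, t, p), pc, rej in zip(raw, p_corr, reject):
                pair_rows.append((a, b, t, p, float(pc), bool(rej)))
        pairwise = pd.DataFrame(
            pair_rows,
            columns=["class_a", "class_b", "t", "p_raw", "p_corrected", "significant"],
        )
        summaries.append(ChipClassSummary(mark=mark, region=region,
                                          class_stats=class_stats,
                                          pairwise=pairwise,
                                          excluded_classes=excluded))
    return summaries
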