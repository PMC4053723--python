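"""Conversion of per-gene AI into XCI statuses and genic aggregation.

Each group 1/2 female gets skew-adjusted AI boundaries: within a sample set
the E1:E2 and E2:E3 boundaries are the 90th and 95th autosomal AI
percentiles, and the E3:S (subject) boundary is the AI that 10% Xi
expression would produce at that female's skew.  For group-2 females all
three boundaries are mapped through the female's regression line against the
group-1 reference.  Low AI means high Xi expression, so a gene is subject
when its mean AI is at or above the subject boundary and escapes otherwise,
graded E1/E2/E3 by the lower boundaries.

Genic statuses aggregate the per-female calls: a gene escapes if >= 7/9 of
informative females escape, is subject if <= 2/9 escape, and variably
escapes in between (exact rational comparisons, honoring the 7-of-9
motivation behind the 78%/22% figures).  Variable-escape genes are subtyped
bimodal / borderline / heterogeneous, and every subject/escape gene gets an
expression class anchored on the %Xi span of the PAR1 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .model import (
    CallLevel,
    ExpressionClass,
    GenicStatus,
    VariableSubtype,
    expected_ai,
    xi_from_ai,
)
from .grouping import AutosomalThresholds, Group1Reference

logger = logging.getLogger(__name__)


@dataclass
class StatusBoundaries:
    """Skew-adjusted AI boundaries for one female: e1_e2 <= e2_e3 <= e3_s."""

    sample: str
    e1_e2: float
    e2_e3: float
    e3_s: float


def female_boundaries(profile: pd.Series, thresholds: AutosomalThresholds,
                      reference: Group1Reference | None = None,
                      xi_cutoff: float = 0.10) -> StatusBoundaries:
    """Boundaries for a group 1 or 2 female.

    Group 1: (q90, q95, expected_ai(skew, xi_cutoff)).  Group 2: each
    group-1-level boundary mapped through the female's regression line
    (slope * boundary + intercept, with the subject boundary taken at the
    reference skew), clipped into [0, 0.5] and re-ordered if the regression
    inverts them (logged).
    """
    group = str(profile["group"])
    if group == "1":
        b = (
            thresholds.q90,
            thresholds.q95,
            expected_ai(profile["skew"], xi_cutoff),
        )
    elif group == "2":
        if reference is None:
            raise ValueError("group-2 boundaries need the group-1 reference")
        slope, intercept = profile["slope"], profile["intercept"]
        group1_e3s = expected_ai(reference.skew, xi_cutoff)
        b = tuple(
            float(np.clip(slope * v + intercept, 0.0, 0.5))
            for v in (thresholds.q90, thresholds.q95, group1_e3s)
        )
        if not (b[0] <= b[1] <= b[2]):
            logger.warning("female %s: regression inverted boundaries %s; re-ordering",
                           profile["sample"], b)
            b = tuple(sorted(b))
    else:
        raise ValueError(f"no boundaries defined for group {group!r} female "
                         f"{profile['sample']!r}")
    return StatusBoundaries(profile["sample"], float(b[0]), float(b[1]), float(b[2]))


def call_gene(ai: float, boundaries: StatusBoundaries, skew: float) -> tuple[CallLevel, float]:
    """Status and %Xi for one gene in one female from its mean AI.

    AI at or above the subject boundary means less than 10% Xi expression
    (ties break to subject); below it the escape grade rises as AI falls.
    """
    if ai >= boundaries.e3_s:
        status = CallLevel.S
    elif ai >= boundaries.e2_e3:
        status = CallLevel.E3
    elif ai >= boundaries.e1_e2:
        status = CallLevel.E2
    else:
        status = CallLevel.E1
    return status, xi_from_ai(min(ai, 0.5), skew)


def call_females(gene_ai: pd.DataFrame, profiles: pd.DataFrame,
                 boundaries: dict[str, StatusBoundaries]) -> pd.DataFrame:
    """Per-(female, gene) calls for all group 1/2 females.

    ``gene_ai`` is the per-(sample, gene) AI table (>= 2 informative probes
    already enforced); females without boundaries (group R) are skipped.
    Returns columns sample, sample_set, gene, n_probes, ai, xi, status.
    """
    skew_by_sample = profiles.set_index("sample")["skew"]
    rows = []
    for _, rec in gene_ai.iterrows():
        b = boundaries.get(rec["sample"])
        if b is None:
            continue
        status, xi = call_gene(float(rec["ai"]), b, float(skew_by_sample[rec["sample"]]))
        rows.append((rec["sample"], rec["sample_set"], rec["gene"],
                     int(rec["n_probes"]), float(rec["ai"]), xi, status.value))
    return pd.DataFrame(
        rows, columns=["sample", "sample_set", "gene", "n_probes", "ai", "xi", "status"]
    )


def variable_subtype(statuses) -> VariableSubtype:
    """Subtype of a variable-escape gene from its per-female call levels."""
    levels = [CallLevel(s) for s in statuses]
    extreme = [s for s in levels if s in (CallLevel.E1, CallLevel.S)]
    has_e1 = CallLevel.E1 in levels
    has_s = CallLevel.S in levels
    if len(extreme) >= 0.75 * len(levels) and has_e1 and has_s:
        return VariableSubtype.BIMODAL
    if all(s in (CallLevel.S, CallLevel.E3) for s in levels):
        return VariableSubtype.BORDERLINE
    return VariableSubtype.HETEROGENEOUS


def aggregate_genic(calls: pd.DataFrame, min_females: int = 1,
                    subject_max: Fraction = Fraction(2, 9),
                    escape_min: Fraction = Fraction(7, 9)) -> pd.DataFrame:
    """Aggregate per-female calls into one genic status per gene.

    Fraction escaping = (# E1/E2/E3 calls) / (# informative females),
    compared with the exact rationals 2/9 and 7/9.  Genes with fewer than
    ``min_females`` informative females are skipped with a log entry.
    Returns gene, n_females, frac_escaping, status, mean_xi, sd_xi, subtype.
    """
    rows = []
    for gene, grp in calls.groupby("gene", sort=True):
        n = len(grp)
        if n < min_females:
            logger.info("gene %s skipped: %d informative female(s) < %d",
                        gene, n, min_females)
            continue
        k = int((grp["status"] != CallLevel.S.value).sum())
        frac = Fraction(k, n)
        if frac >= escape_min:
            status = GenicStatus.ESCAPE
        elif frac <= subject_max:
            status = GenicStatus.SUBJECT
        else:
            status = GenicStatus.VARIABLE_ESCAPE
        subtype = (
            variable_subtype(grp["status"]).value
            if status is GenicStatus.VARIABLE_ESCAPE else ""
        )
        xi = grp["xi"].to_numpy(dtype=float)
        rows.append((gene, n, float(frac), status.value, float(xi.mean()),
                     float(xi.std(ddof=1)) if n > 1 else 0.0, subtype))
    return pd.DataFrame(
        rows,
        columns=["gene", "n_females", "frac_escaping", "status",
                 "mean_xi", "sd_xi", "subtype"],
    )


def par1_range_classes(genic: pd.DataFrame, par1_genes,
                       subject_split: float = 0.05) -> pd.DataFrame:
    """Assign expression classes anchored on the PAR1 genes' mean %Xi span.

    Escape genes whose mean %Xi reaches the minimum of the PAR1 range are
    ``escape_in_PAR1_range``; other escape genes are outside the range.
    Subject genes split at mean %Xi ``subject_split`` (>= is the higher
    class, as the boundary is inclusive).  Variable-escape genes get no
    class.  With no informative PAR1 gene the escape classes collapse (all
    escape genes in-range is meaningless, so they are left unclassed) with a
    warning.
    """
    par1 = set(par1_genes)
    genic = genic.copy()
    par1_xi = genic.loc[genic["gene"].isin(par1), "mean_xi"]
    par1_min = float(par1_xi.min()) if not par1_xi.empty else None
    if par1_min is None:
        logger.warning("no informative PAR1 gene: escape genes left without a "
                       "PAR1-range class")

    def classify(rec) -> str:
        if rec["status"] == GenicStatus.ESCAPE.value:
            if par1_min is None:
                return "escape_unclassed"
            return (
                ExpressionClass.ESCAPE_IN_PAR1_RANGE.value
                if rec["mean_xi"] >= par1_min
                else ExpressionClass.ESCAPE_OUTSIDE_PAR1_RANGE.value
            )
        if rec["status"] == GenicStatus.SUBJECT.value:
            return (
                ExpressionClass.SUBJECT_GE5.value
                if rec["mean_xi"] >= subject_split
                else ExpressionClass.SUBJECT_LT5.value
            )
        return ""

    genic["expression_class"] = genic.apply(classify, axis=1)
    return genic


def consistent_reference(group1_calls: pd.DataFrame, gene_ai: pd.DataFrame,
                         profiles: pd.DataFrame, sample_set: str,
                         subject_max: Fraction = Fraction(2, 9),
                         escape_min: Fraction = Fraction(7, 9)) -> Group1Reference:
    """Build the group-2 regression reference for one sample set.

    Consistent genes are those whose genic call over the set's group-1
    females is subject or escape (never variable); the reference profile is
    the mean per-gene AI of the group-1 females over those genes, and the
    reference skew the mean estimated skew of those females.
    """
    genic = aggregate_genic(group1_calls, min_females=1,
                            subject_max=subject_max, escape_min=escape_min)
    consistent = set(
        genic.loc[genic["status"] != GenicStatus.VARIABLE_ESCAPE.value, "gene"]
    )
    g1 = profiles[(profiles["sample_set"] == sample_set) & (profiles["group"] == "1")]
    sub = gene_ai[
        gene_ai["sample"].isin(g1["sample"]) & gene_ai["gene"].isin(consistent)
    ]
    means = sub.groupby("gene", sort=True)["ai"].mean()
    skew = float(g1["skew"].mean()) if not g1.empty else float("nan")
    return Group1Reference(gene_means=means, skew=skew, sample_set=sample_set)
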