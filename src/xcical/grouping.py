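"""Per-female skewing estimation and group 1 / 2 / R classification.

Skewing of XCI is estimated per female as the mean genic AI over a *subject
training set* -- genes reliably silenced on the Xi -- using only genes with
at least two informative probes in that female.  Females whose average
subject AI exceeds the sample set's 99.5th autosomal AI percentile are the
most highly skewed (group 1).  The remaining females are regressed, gene by
gene, against the mean AI profile of the group-1 females over genes with a
consistent XCI pattern; a significant slope marks a female as detectably
skewed (group 2), otherwise her XCI is effectively random (group R) and AI
carries no XCI information.  Group R females are screened for outliers with
a Grubbs test before being used in the imprinting analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import skew_from_subject_ai

logger = logging.getLogger(__name__)


@dataclass
class AutosomalThresholds:
    """Per-sample-set autosomal AI quantiles: q90 <= q95 <= q995."""

    q90: float
    q95: float
    q995: float
    sample_set: str = ""

    def __post_init__(self) -> None:
        if not self.q90 <= self.q95 <= self.q995:
            raise ValueError(
                f"autosomal thresholds must be ordered, got "
                f"q90={self.q90}, q95={self.q95}, q995={self.q995}"
            )


def autosomal_thresholds(autosomal_ai: pd.DataFrame, q_e1: float = 0.90,
                         q_e2: float = 0.95, q_mono: float = 0.995,
                         ) -> dict[str, AutosomalThresholds]:
    """AI quantiles of informative autosomal probes, per sample set.

    ``autosomal_ai`` needs columns sample_set and ai.
    """
    out: dict[str, AutosomalThresholds] = {}
    for sset, grp in autosomal_ai.groupby("sample_set", sort=True):
        vals = grp["ai"].to_numpy(dtype=float)
        q90, q95, q995 = np.quantile(vals, [q_e1, q_e2, q_mono])
        out[sset] = AutosomalThresholds(float(q90), float(q95), float(q995), sset)
    return out


@dataclass
class Group1Reference:
    """Per-set regression reference built from group-1 females.

    ``gene_means`` is the mean per-gene AI across the set's group-1 females,
    restricted to genes with a consistent XCI pattern (genic call subject or
    escape, never variable); ``skew`` is the mean estimated skew of those
    females, used to place the subject boundary at the group-1 level.
    """

    gene_means: pd.Series
    skew: float
    sample_set: str = ""


def average_training_ai(female_gene_ai: pd.DataFrame, training_genes,
                        min_probes: int = 2) -> float:
    """Mean over training genes of the per-gene mean AI for one female.

    ``female_gene_ai`` holds one female's rows of the per-(sample, gene) AI
    table (columns gene, n_probes, ai).  Genes need ``min_probes``
    informative probes to count; returns NaN when no gene qualifies.
    """
    training = set(training_genes)
    rows = female_gene_ai[
        female_gene_ai["gene"].isin(training)
        & (female_gene_ai["n_probes"] >= min_probes)
    ]
    if rows.empty:
        return float("nan")
    return float(rows["ai"].mean())


def build_profiles(gene_ai: pd.DataFrame, subject_genes,
                   samples: pd.DataFrame, min_probes: int = 2) -> pd.DataFrame:
    """Initial per-female profiles: sample, sample_set, avg_subject_ai.

    ``samples`` lists every female (columns sample, sample_set) so females
    with no qualifying training gene still appear (avg_subject_ai = NaN).
    """
    rows = []
    by_sample = dict(tuple(gene_ai.groupby("sample"))) if not gene_ai.empty else {}
    for _, rec in samples.iterrows():
        fga = by_sample.get(rec["sample"])
        avg = (
            average_training_ai(fga, subject_genes, min_probes)
            if fga is not None else float("nan")
        )
        rows.append((rec["sample"], rec["sample_set"], avg))
    return pd.DataFrame(rows, columns=["sample", "sample_set", "avg_subject_ai"])


def classify_groups(profiles: pd.DataFrame,
                    thresholds: dict[str, AutosomalThresholds],
                    references: dict[str, Group1Reference],
                    gene_ai: pd.DataFrame,
                    alpha: float = 0.05,
                    min_regression_genes: int = 3) -> pd.DataFrame:
    """Assign each female to group 1, 2 or R.

    Group 1: average subject-training AI strictly greater than the set's
    q995.  Otherwise the female's per-gene AI is regressed on the group-1
    reference means over consistent genes; a slope significant at ``alpha``
    makes her group 2 (slope/intercept stored for boundary rescaling), else
    group R.  Sets without a group-1 reference get all non-group-1 females
    assigned to group R with a warning.  Skew (0.5 + avg subject AI) is
    defined for groups 1 and 2 only.
    """
    prof = profiles.copy()
    for col, default in (("group", "R"), ("skew", np.nan), ("slope", np.nan),
                         ("intercept", np.nan), ("p_value", np.nan),
                         ("excluded_outlier", False)):
        prof[col] = default

    by_sample = dict(tuple(gene_ai.groupby("sample"))) if not gene_ai.empty else {}
    warned_sets: set[str] = set()
    for idx, rec in prof.iterrows():
        sset = rec["sample_set"]
        thr = thresholds[sset]
        avg = rec["avg_subject_ai"]
        if np.isfinite(avg) and avg > thr.q995:
            prof.loc[idx, "group"] = "1"
            prof.loc[idx, "skew"] = skew_from_subject_ai(min(avg, 0.5))
            continue
        ref = references.get(sset)
        if ref is None or ref.gene_means.empty:
            if sset not in warned_sets:
                logger.warning(
                    "sample set %s has no group-1 reference; all non-group-1 "
                    "females assigned to group R", sset,
                )
                warned_sets.add(sset)
            continue
        fga = by_sample.get(rec["sample"])
        if fga is None:
            continue
        joined = fga.set_index("gene")["ai"].reindex(ref.gene_means.index).dropna()
        x = ref.gene_means.loc[joined.index].to_numpy(dtype=float)
        y = joined.to_numpy(dtype=float)
        if len(x) < min_regression_genes or np.ptp(x) <= 0:
            continue
        fit = stats.linregress(x, y)
        prof.loc[idx, ["slope", "intercept", "p_value"]] = (
            fit.slope, fit.intercept, fit.pvalue,
        )
        if fit.pvalue <= alpha:
            prof.loc[idx, "group"] = "2"
            if np.isfinite(avg):
                prof.loc[idx, "skew"] = skew_from_subject_ai(min(max(avg, 0.0), 0.5))
    return prof


@dataclass
class GrubbsResult:
    """One-sided maximum-deviation Grubbs outlier screen."""

    z: float
    critical: float
    outliers: list[str]
    applicable: bool = True


def grubbs_critical(n: int, alpha: float = 0.05, two_sided: bool = False) -> float:
    """Critical value of the Grubbs statistic for a single outlier test."""
    p = alpha / n if not two_sided else alpha / (2 * n)
    t = stats.t.ppf(1.0 - p, n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_outlier(values: pd.Series, alpha: float = 0.05,
                   two_sided: bool = False) -> GrubbsResult:
    """Single-outlier Grubbs test on a labelled series.

    One-sided toward high values by default (the direction in which an
    imprinting-like signal would pull a group-R female's average AI); at
    most one sample is flagged per call, matching the screen's use of the
    test to drop the single extreme female.  Requires n >= 3; with zero
    spread Z is defined as 0 and nothing is flagged.
    """
    series = values.dropna().astype(float)
    n = len(series)
    if n < 3:
        return GrubbsResult(z=float("nan"), critical=float("nan"),
                            outliers=[], applicable=False)
    mean = series.mean()
    sd = series.std(ddof=1)
    if sd == 0:
        z, label = 0.0, None
    elif two_sided:
        dev = (series - mean).abs()
        label = dev.idxmax()
        z = float(dev.max() / sd)
    else:
        label = series.idxmax()
        z = float((series.max() - mean) / sd)
    crit = grubbs_critical(n, alpha, two_sided)
    outliers = [label] if (label is not None and z > crit) else []
    return GrubbsResult(z=z, critical=crit, outliers=outliers)
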