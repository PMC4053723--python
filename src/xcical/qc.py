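"""Probe quality control.

Three exclusion rules precede any XCI calling:

* a minimum total-cDNA intensity per sample set, set to the decay constant
  Tau of a one-phase exponential decay fitted to the AI of homozygous
  (uninformative) probes against intensity -- below Tau, hybridization noise
  produces spurious imbalance;
* removal of probes whose genomic-DNA allele ratio exceeds 0.7 in at least
  50% of informative females of any one sample set (excluded in all sets);
* a concordance check for genes measured by exactly two probes, flagging
  genes enriched for discordant probe-level calls.

The first two rules are exposed both as plain functions and as sklearn-style
transformers so they compose with pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._util import ai_of_fraction, expression_rows, uninformative_ai


class DecayFitError(RuntimeError):
    """One-phase decay fit failed to converge for a sample set."""


class DegenerateDecayError(DecayFitError):
    """AI shows no intensity dependence; Tau is undefined."""


@dataclass
class DecayFit:
    """One-phase exponential decay AI(I) = plateau + (y0 - plateau) exp(-I/tau).

    ``tau`` (intensity units) is used as the minimum total-cDNA threshold.
    """

    y0: float
    plateau: float
    tau: float
    r_squared: float
    n: int
    sample_set: str = ""

    def predict(self, intensity):
        i = np.asarray(intensity, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-i / self.tau)


def _decay_model(intensity, y0, plateau, tau):
    return plateau + (y0 - plateau) * np.exp(-intensity / tau)


def fit_intensity_decay(uninformative: pd.DataFrame, sample_set: str = "",
                        min_probes: int = 20) -> DecayFit:
    """Fit the one-phase decay of homozygous-probe AI against total intensity.

    ``uninformative`` is a probe table restricted to homozygous rows; the AI
    of a homozygote is its deviation from the clean mono-allelic signal,
    min(f, 1-f).
    """
    intensity = uninformative["intensity"].to_numpy(dtype=float)
    ai = uninformative_ai(uninformative["frac_expr"])
    if len(intensity) < min_probes:
        raise DecayFitError(
            f"sample set {sample_set!r}: need >= {min_probes} uninformative probes, "
            f"got {len(intensity)}"
        )
    if np.ptp(intensity) <= 0:
        raise DecayFitError(f"sample set {sample_set!r}: intensities span no range")
    if np.std(ai) < 1e-12:
        raise DegenerateDecayError(
            f"sample set {sample_set!r}: AI is constant, no decay to fit"
        )

    # initialisation from decile means: y0 from the lowest-intensity decile,
    # plateau from the highest, tau where the decile profile crosses halfway
    order = np.argsort(intensity)
    deciles = np.array_split(order, 10)
    dec_int = np.array([intensity[idx].mean() for idx in deciles])
    dec_ai = np.array([ai[idx].mean() for idx in deciles])
    y0_init = float(dec_ai[0])
    plateau_init = float(dec_ai[-1])
    halfway = (y0_init + plateau_init) / 2.0
    below = np.flatnonzero(dec_ai <= halfway)
    tau_init = float(dec_int[below[0]]) if below.size else float(np.median(intensity))
    tau_init = max(tau_init, 1e-6)

    try:
        popt, _ = optimize.curve_fit(
            _decay_model, intensity, ai,
            p0=(y0_init, plateau_init, tau_init),
            bounds=([0.0, 0.0, 1e-9], [0.5, 0.5, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise DecayFitError(f"sample set {sample_set!r}: decay fit did not converge") from exc
    y0, plateau, tau = (float(v) for v in popt)
    if y0 <= plateau + 1e-9:
        raise DegenerateDecayError(
            f"sample set {sample_set!r}: fitted curve does not decay (y0 <= plateau)"
        )
    resid = ai - _decay_model(intensity, *popt)
    ss_tot = float(np.sum((ai - ai.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return DecayFit(y0=y0, plateau=plateau, tau=tau, r_squared=r2,
                    n=len(intensity), sample_set=sample_set)


def fit_decay_per_set(probes: pd.DataFrame, min_probes: int = 20) -> dict[str, DecayFit]:
    """Fit the intensity decay separately for every sample set present."""
    expr = expression_rows(probes)
    uninf = expr[expr["informative"] == 0]
    fits: dict[str, DecayFit] = {}
    for sset, group in uninf.groupby("sample_set", sort=True):
        fits[sset] = fit_intensity_decay(group, sample_set=sset, min_probes=min_probes)
    return fits


@dataclass
class ProbeFilterReport:
    """Excluded rows/probes per rule, plus the surviving table.

    ``exclusions`` has columns probe_id, sample, sample_set, rule; excluded
    and surviving rows partition the input.
    """

    surviving: pd.DataFrame
    exclusions: pd.DataFrame
    taus: dict[str, float] = field(default_factory=dict)
    flagged_probes: list[str] = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        if self.exclusions.empty:
            return pd.DataFrame(columns=["sample_set", "rule", "n_excluded"])
        return (
            self.exclusions.groupby(["sample_set", "rule"], sort=True)
            .size()
            .rename("n_excluded")
            .reset_index()
        )


def apply_intensity_filter(probes: pd.DataFrame, taus: dict[str, float]) -> ProbeFilterReport:
    """Retain rows with total cDNA intensity strictly greater than the set's Tau."""
    sets_present = probes["sample_set"].unique()
    missing = [s for s in sets_present if s not in taus]
    if missing:
        raise ValueError(f"no Tau available for sample sets {missing}")
    tau_col = probes["sample_set"].map(taus).astype(float)
    keep = probes["intensity"] > tau_col
    excluded = probes.loc[~keep, ["probe_id", "sample", "sample_set"]].copy()
    excluded["rule"] = "low_intensity"
    return ProbeFilterReport(
        surviving=probes.loc[keep].reset_index(drop=True),
        exclusions=excluded.reset_index(drop=True),
        taus=dict(taus),
    )


def flag_gdna_biased_probes(probes: pd.DataFrame, ratio_max: float = 0.7,
                            prevalence: float = 0.5) -> list[str]:
    """Probes with a skewed genomic-DNA ratio, excluded globally.

    A probe is flagged when, in ANY single sample set, at least ``prevalence``
    of its informative females show max(ratio, 1-ratio) > ``ratio_max``; the
    symmetric form makes the rule invariant to allele labelling.
    """
    expr = expression_rows(probes)
    inf = expr[expr["informative"] == 1]
    if inf.empty:
        return []
    g = inf["frac_gdna"].to_numpy(dtype=float)
    biased = np.maximum(g, 1.0 - g) > ratio_max
    frac = (
        inf.assign(_biased=biased)
        .groupby(["probe_id", "sample_set"], sort=True)["_biased"]
        .mean()
    )
    flagged = frac[frac >= prevalence].index.get_level_values("probe_id")
    return sorted(set(flagged))


def apply_probe_exclusion(probes: pd.DataFrame, flagged_probes) -> ProbeFilterReport:
    """Drop every row of the flagged probes, in all sample sets."""
    flagged = set(flagged_probes)
    drop = probes["probe_id"].isin(flagged)
    excluded = probes.loc[drop, ["probe_id", "sample", "sample_set"]].copy()
    excluded["rule"] = "gdna_ratio"
    return ProbeFilterReport(
        surviving=probes.loc[~drop].reset_index(drop=True),
        exclusions=excluded.reset_index(drop=True),
        flagged_probes=sorted(flagged),
    )


class IntensityDecayFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: learn per-set Tau thresholds, drop dim probes.

    ``fit`` estimates one decay fit per sample set from the homozygous rows;
    ``transform`` keeps rows with intensity strictly above the set's Tau.
    """

    def __init__(self, min_probes: int = 20):
        self.min_probes = min_probes

    def fit(self, X: pd.DataFrame, y=None):
        self.fits_ = fit_decay_per_set(X, min_probes=self.min_probes)
        self.taus_ = {s: f.tau for s, f in self.fits_.items()}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        report = apply_intensity_filter(X, self.taus_)
        self.report_ = report
        return report.surviving


class GenomicRatioFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for the genomic-DNA ratio exclusion rule."""

    def __init__(self, ratio_max: float = 0.7, prevalence: float = 0.5):
        self.ratio_max = ratio_max
        self.prevalence = prevalence

    def fit(self, X: pd.DataFrame, y=None):
        self.flagged_probes_ = flag_gdna_biased_probes(
            X, ratio_max=self.ratio_max, prevalence=self.prevalence
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        report = apply_probe_exclusion(X, self.flagged_probes_)
        self.report_ = report
        return report.surviving


def probe_concordance(probe_calls: pd.DataFrame, e3_s_by_sample: dict[str, float],
                      mode: str = "status", delta: float = 0.1,
                      alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Concordance of the two probes of two-probe genes, per female.

    ``probe_calls`` needs columns gene, sample, probe_id, ai and must be
    restricted to informative, surviving probes.  Two probes are concordant
    in a female either when they fall on the same side of that female's
    subject boundary (``mode="status"``: same S-vs-escape call) or when
    their AIs differ by less than ``delta`` (``mode="delta"``).  Each gene's
    discordant count is compared with the cohort-wide discordance rate by a
    chi-square goodness-of-fit test; a gene is flagged when it is enriched
    for discordance at ``alpha``.

    Returns the per-gene table and a summary dict (cohort concordance,
    discordance rate, number flagged, mode).
    """
    if mode not in ("status", "delta"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    counts = probe_calls.groupby("gene")["probe_id"].nunique()
    two_probe_genes = counts[counts == 2].index
    sub = probe_calls[probe_calls["gene"].isin(two_probe_genes)]

    records = []
    for (gene, sample), grp in sub.groupby(["gene", "sample"], sort=True):
        if grp["probe_id"].nunique() != 2:
            continue  # only one of the two probes informative in this female
        ai = grp["ai"].to_numpy(dtype=float)[:2]
        if mode == "delta":
            concordant = abs(ai[0] - ai[1]) < delta
        else:
            boundary = e3_s_by_sample.get(sample)
            if boundary is None:
                continue  # no boundaries (group R female)
            concordant = (ai[0] >= boundary) == (ai[1] >= boundary)
        records.append((gene, sample, bool(concordant)))
    pairs = pd.DataFrame(records, columns=["gene", "sample", "concordant"])
    if pairs.empty:
        return (
            pd.DataFrame(columns=["gene", "n_females", "n_discordant",
                                  "concordance", "p_value", "enriched"]),
            {"concordance": np.nan, "discordance_rate": np.nan,
             "n_flagged": 0, "mode": mode},
        )

    p0 = 1.0 - pairs["concordant"].mean()
    per_gene = []
    for gene, grp in pairs.groupby("gene", sort=True):
        n = len(grp)
        k = int((~grp["concordant"]).sum())
        if 0.0 < p0 < 1.0:
            expected = np.array([n * p0, n * (1.0 - p0)])
            observed = np.array([k, n - k])
            stat = float(np.sum((observed - expected) ** 2 / expected))
            p = float(stats.chi2.sf(stat, df=1))
        else:
            p = 1.0
        enriched = (p < alpha) and (k / n > p0)
        per_gene.append((gene, n, k, 1.0 - k / n, p, enriched))
    table = pd.DataFrame(
        per_gene,
        columns=["gene", "n_females", "n_discordant", "concordance", "p_value", "enriched"],
    )
    summary = {
        "concordance": float(pairs["concordant"].mean()),
        "discordance_rate": float(p0),
        "n_flagged": int(table["enriched"].sum()),
        "mode": mode,
    }
    return table, summary
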