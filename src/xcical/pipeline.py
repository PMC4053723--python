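"""End-to-end pipeline: probe QC -> female grouping -> XCI calls -> analyses.

Stage order mirrors the method: probes failing the intensity (Tau) or
genomic-DNA ratio rules are excluded; per-female skewing is estimated from
the subject training set and females classified into groups 1/2/R; AI is
converted to per-female statuses with skew-adjusted boundaries and
aggregated into genic statuses; downstream come the adjacency clustering
test, the cross-sample-set comparison, the group-R mono-allelic screen
(after a Grubbs outlier exclusion) and, when ChIP data are present, the
histone-mark class comparison.  Any stage failure aborts with a
stage-named error and nothing is written, so output directories are never
left half-populated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import autosomal_ai_values, gene_ai_table, stable_hash
from .analyses import (
    adjacency_chi_square,
    adjacency_counts,
    chip_class_compare,
    cross_set_table,
    group_r_allelic,
    permutation_expected,
)
from .calling import (
    aggregate_genic,
    call_females,
    consistent_reference,
    female_boundaries,
    par1_range_classes,
)
from .config import PipelineConfig
from .grouping import (
    autosomal_thresholds,
    build_profiles,
    classify_groups,
    grubbs_outlier,
)
from .io import write_table
from .qc import (
    GenomicRatioFilter,
    IntensityDecayFilter,
    probe_concordance,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    """All pipeline outputs, written to disk only on success."""

    filter_report: pd.DataFrame
    profiles: pd.DataFrame
    boundaries: pd.DataFrame
    calls: pd.DataFrame
    genic: pd.DataFrame
    concordance: pd.DataFrame
    adjacency: pd.DataFrame
    adjacency_summary: dict
    cross_set: pd.DataFrame
    group_r_calls: pd.DataFrame
    group_r_genic: pd.DataFrame
    chip_class_stats: pd.DataFrame
    chip_pairwise: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = "\n".join(f"{k}={v}" for k, v in sorted(self.metadata.items()))
        tables = {
            "filter_report.tsv": self.filter_report,
            "female_profiles.tsv": self.profiles,
            "boundaries.tsv": self.boundaries,
            "gene_calls.tsv": self.calls,
            "genic_status.tsv": self.genic,
            "probe_concordance.tsv": self.concordance,
            "adjacency.tsv": self.adjacency,
            "cross_set.tsv": self.cross_set,
            "group_r_calls.tsv": self.group_r_calls,
            "group_r_genic.tsv": self.group_r_genic,
            "chip_class_stats.tsv": self.chip_class_stats,
            "chip_pairwise.tsv": self.chip_pairwise,
        }
        for name, df in tables.items():
            write_table(df, outdir / name, header_comment=header)
        with open(outdir / "run_metadata.txt", "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"{k}\t{v}\n")
            for k, v in sorted(self.adjacency_summary.items()):
                fh.write(f"adjacency_{k}\t{v}\n")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(probes: pd.DataFrame, annotation: pd.DataFrame,
                 subject_genes, escape_genes=(),
                 chip: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    # accept annotation frames with or without a gene index
    annotation = annotation.reset_index(drop="gene" in annotation.columns)
    meta = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": stable_hash(cfg.to_dict()),
        "concordance_mode": cfg.concordance_mode,
        "correction": cfg.correction,
        "group_r_scaling": "per-set q995, no cross-set rescaling",
    }

    # --- probe QC -----------------------------------------------------------
    @_stage("probe_qc")
    def do_qc():
        intensity = IntensityDecayFilter(min_probes=cfg.min_decay_probes)
        surviving = intensity.fit_transform(probes)
        gdna = GenomicRatioFilter(ratio_max=cfg.gdna_ratio_max,
                                  prevalence=cfg.gdna_prevalence)
        surviving = gdna.fit_transform(surviving)
        report = pd.concat(
            [intensity.report_.exclusions, gdna.report_.exclusions],
            ignore_index=True,
        )
        return surviving, report, intensity.taus_, gdna.flagged_probes_

    surviving, filter_report, taus, flagged = do_qc()
    meta.update({f"tau_{s}": f"{t:.6g}" for s, t in sorted(taus.items())})
    meta["n_gdna_flagged_probes"] = len(flagged)

    # --- thresholds and grouping -------------------------------------------
    @_stage("female_grouping")
    def do_grouping():
        auto = autosomal_ai_values(surviving)
        if auto.empty:
            raise ValueError("no informative autosomal probes survive QC")
        thresholds = autosomal_thresholds(auto, cfg.q_e1, cfg.q_e2, cfg.q_mono)
        gene_ai = gene_ai_table(surviving, min_probes=cfg.min_probes_per_gene)
        samples = (
            surviving.loc[surviving["sex"] == "F", ["sample", "sample_set"]]
            .drop_duplicates()
            .sort_values("sample")
        )
        profiles = build_profiles(gene_ai, subject_genes, samples,
                                  cfg.min_probes_per_gene)
        # provisional pass: group-1 assignment only, to build the per-set
        # regression references (no warnings about missing references yet)
        refs = {}
        prof1 = profiles.copy()
        q995 = prof1["sample_set"].map({s: t.q995 for s, t in thresholds.items()})
        is_g1 = prof1["avg_subject_ai"].gt(q995) & prof1["avg_subject_ai"].notna()
        prof1["group"] = np.where(is_g1, "1", "R")
        prof1["skew"] = np.where(
            is_g1, 0.5 + prof1["avg_subject_ai"].clip(upper=0.5), np.nan
        )
        for sset in sorted(samples["sample_set"].unique()):
            g1 = prof1[(prof1["sample_set"] == sset) & (prof1["group"] == "1")]
            if g1.empty:
                continue
            b = {
                rec["sample"]: female_boundaries(rec, thresholds[sset],
                                                 xi_cutoff=cfg.xi_escape_cutoff)
                for _, rec in g1.iterrows()
            }
            g1_calls = call_females(
                gene_ai[gene_ai["sample"].isin(g1["sample"])], prof1, b
            )
            refs[sset] = consistent_reference(
                g1_calls, gene_ai, prof1, sset,
                cfg.genic_subject_max, cfg.genic_escape_min,
            )
        profiles = classify_groups(profiles, thresholds, refs, gene_ai, cfg.alpha)
        return thresholds, gene_ai, profiles, refs

    thresholds, gene_ai, profiles, refs = do_grouping()

    # --- per-female boundaries and calls ------------------------------------
    @_stage("xci_calling")
    def do_calling():
        boundaries = {}
        brows = []
        for _, rec in profiles.iterrows():
            if rec["group"] not in ("1", "2"):
                continue
            ref = refs.get(rec["sample_set"])
            if rec["group"] == "2" and ref is None:
                continue
            b = female_boundaries(rec, thresholds[rec["sample_set"]],
                                  reference=ref, xi_cutoff=cfg.xi_escape_cutoff)
            boundaries[rec["sample"]] = b
            brows.append((rec["sample"], rec["sample_set"], rec["group"],
                          b.e1_e2, b.e2_e3, b.e3_s))
        btable = pd.DataFrame(
            brows, columns=["sample", "sample_set", "group", "e1_e2", "e2_e3", "e3_s"]
        )
        calls = call_females(gene_ai, profiles, boundaries)
        if calls.empty:
            logger.warning("no group 1/2 females: genic table will be empty")
            genic = pd.DataFrame(columns=["gene", "n_females", "frac_escaping",
                                          "status", "mean_xi", "sd_xi", "subtype",
                                          "expression_class"])
        else:
            genic = aggregate_genic(calls, cfg.min_females_genic,
                                    cfg.genic_subject_max, cfg.genic_escape_min)
            par1_ids = annotation.loc[annotation["par1"] == 1, "gene"]
            genic = par1_range_classes(genic, par1_ids, cfg.subject_class_split)
        return boundaries, btable, calls, genic

    boundaries, btable, calls, genic = do_calling()

    # --- probe concordance ---------------------------------------------------
    @_stage("probe_concordance")
    def do_concordance():
        from ._util import ai_of_fraction, informative_x_rows
        rows = informative_x_rows(surviving)
        pc = rows.assign(ai=ai_of_fraction(rows["frac_expr"]))[
            ["gene", "sample", "probe_id", "ai"]
        ]
        e3s = {s: b.e3_s for s, b in boundaries.items()}
        table, summary = probe_concordance(
            pc, e3s, mode=cfg.concordance_mode,
            delta=cfg.concordance_delta, alpha=cfg.alpha,
        )
        return table, summary

    concordance, conc_summary = do_concordance()
    meta["concordance_fraction"] = f"{conc_summary['concordance']:.4f}" \
        if np.isfinite(conc_summary["concordance"]) else "NA"

    # --- adjacency clustering ------------------------------------------------
    @_stage("adjacency")
    def do_adjacency():
        classified = genic[genic["status"].notna() & (genic["gene"] != "")]
        par1_ids = set(annotation.loc[annotation["par1"] == 1, "gene"])
        positions = annotation.set_index("gene")["start"]
        if len(classified) < 2:
            return (pd.DataFrame(columns=["pair", "observed", "expected",
                                          "component", "std_residual"]),
                    {"statistic": float("nan"), "p_value": float("nan"),
                     "empirical_p": float("nan"), "df": 0})
        observed = adjacency_counts(classified, positions, par1_ids)
        expected, p_emp = permutation_expected(
            classified, positions, cfg.n_permutations, cfg.seed, par1_ids,
        )
        result = adjacency_chi_square(observed, expected, df=cfg.adjacency_df)
        summary = {"statistic": f"{result.statistic:.4f}", "df": result.df,
                   "p_value": f"{result.p_value:.6g}", "empirical_p": f"{p_emp:.6g}"}
        return result.table, summary

    adjacency, adjacency_summary = do_adjacency()

    # --- cross-sample-set comparison ----------------------------------------
    @_stage("cross_set")
    def do_cross_set():
        if calls.empty:
            return pd.DataFrame(columns=["gene", "category"])
        return cross_set_table(
            calls, cfg.min_females_per_set, cfg.same_cell_type_sets,
            cfg.other_cell_type_set, cfg.genic_subject_max, cfg.genic_escape_min,
        )

    cross_set = do_cross_set()

    # --- group R: outlier screen + mono-allelic analysis ---------------------
    @_stage("group_r")
    def do_group_r():
        prof = profiles.copy()
        group_r = prof[prof["group"] == "R"]
        keep_samples = []
        for sset, grp in group_r.groupby("sample_set"):
            res = grubbs_outlier(grp.set_index("sample")["avg_subject_ai"],
                                 cfg.alpha, cfg.grubbs_two_sided)
            prof.loc[prof["sample"].isin(res.outliers), "excluded_outlier"] = True
            keep_samples.extend(s for s in grp["sample"] if s not in res.outliers)
        q995 = {s: t.q995 for s, t in thresholds.items()}
        r_calls, r_genic = group_r_allelic(
            gene_ai, keep_samples, q995,
            cfg.genic_subject_max, cfg.genic_escape_min,
        )
        return prof, r_calls, r_genic

    profiles, group_r_calls, group_r_genic = do_group_r()

    # --- histone ChIP class comparison ---------------------------------------
    @_stage("chip")
    def do_chip():
        if chip is None or chip.empty or genic.empty:
            return (pd.DataFrame(columns=["mark", "region", "expression_class",
                                          "n", "mean_ai", "sem"]),
                    pd.DataFrame(columns=["mark", "region", "class_a", "class_b",
                                          "t", "p_raw", "p_corrected", "significant"]))
        classes = genic.set_index("gene")["expression_class"]
        summaries = chip_class_compare(chip, annotation, classes,
                                       cfg.promoter_window, cfg.correction,
                                       cfg.alpha)
        stats_rows, pair_rows = [], []
        for s in summaries:
            stats_rows.append(s.class_stats.assign(mark=s.mark, region=s.region))
            if not s.pairwise.empty:
                pair_rows.append(s.pairwise.assign(mark=s.mark, region=s.region))
        chip_stats = (pd.concat(stats_rows, ignore_index=True)
                      [["mark", "region", "expression_class", "n", "mean_ai", "sem"]]
                      if stats_rows else
                      pd.DataFrame(columns=["mark", "region", "expression_class",
                                            "n", "mean_ai", "sem"]))
        chip_pairs = (pd.concat(pair_rows, ignore_index=True)
                      [["mark", "region", "class_a", "class_b", "t",
                        "p_raw", "p_corrected", "significant"]]
                      if pair_rows else
                      pd.DataFrame(columns=["mark", "region", "class_a", "class_b",
                                            "t", "p_raw", "p_corrected", "significant"]))
        return chip_stats, chip_pairs

    chip_stats, chip_pairs = do_chip()

    return PipelineResult(
        filter_report=filter_report,
        profiles=profiles,
        boundaries=btable,
        calls=calls,
        genic=genic,
        concordance=concordance,
        adjacency=adjacency,
        adjacency_summary=adjacency_summary,
        cross_set=cross_set,
        group_r_calls=group_r_calls,
        group_r_genic=group_r_genic,
        chip_class_stats=chip_stats,
        chip_pairwise=chip_pairs,
        metadata=meta,
    )
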