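"""Synthetic cohort generator.

Emulates the statistical structure the pipeline assumes so every stage is
testable without array data: three sample sets of females whose XCI skewing
spans random to near-complete (a three-component Beta mixture); X-linked
genes with true Xi-expression architectures laid out in positional runs
along the chromosome (subject ~0, escape broad up to a PAR1-like 0.49-0.75
band, and variable-escape genes with bimodal / borderline / heterogeneous
per-female behaviour); 1-10 probes per gene with per-female heterozygosity;
AI measurement noise whose standard deviation decays exponentially with
total intensity (log-normal intensities), so the Tau QC filter has something
real to find; a small fraction of probes with genomic-DNA ratio artifacts;
an autosomal background that is mostly balanced with a ~10% imbalanced
minority (which is what puts the 90/95/99.5 autosomal percentiles where the
calling rules need them); a few genes with population- or cell-line-specific
XCI; one imprinted gene that is mono-allelic regardless of skew; and histone
ChIP-AI values anticorrelated with Xi expression.

Informative probes follow the forward model exactly: allele-1 fraction
f = (s + e(1-s)) / (1+e) at the female's true skew s and the gene's true
Xi/Xa ratio e, plus intensity-dependent noise, truncated to [0, 1].
Homozygous (uninformative) probes have a true fraction of 0 or 1 observed
with the same noise.  All randomness flows from one seeded generator, so an
identical config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import AUTOSOME_MARKER, EXPRESSION_CHANNEL
from .io import PROBE_COLUMNS
from .model import ExpressionClass, GenicStatus, VariableSubtype, expected_ai

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class CohortConfig:
    """Generator settings; defaults are the cohort the pipeline is tested on."""

    sample_sets: tuple[str, ...] = ("LCL1", "LCL2", "FIB")
    n_females_per_set: int = 20
    n_x_genes: int = 200
    n_par1_genes: int = 8
    n_subject_training: int = 100
    n_escape_training: int = 30
    n_autosomal_probes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 10)
    heterozygosity_rate: float = 0.3
    # skewing mixture: skew = 0.5 + 0.5 * Beta(a, b) per component
    frac_high_skew: float = 0.35
    frac_moderate_skew: float = 0.35
    high_skew_beta: tuple[float, float] = (9.0, 1.5)
    moderate_skew_beta: tuple[float, float] = (4.0, 4.0)
    random_skew_beta: tuple[float, float] = (1.0, 12.0)
    skew_values: tuple[float, ...] | None = None   # explicit override, one per female
    # XCI architecture (fractions of non-PAR1 genes)
    subject_fraction: float = 0.60
    escape_fraction: float = 0.12
    subject_zero_fraction: float = 0.75
    subject_low_xi: tuple[float, float] = (0.02, 0.09)
    escape_xi: tuple[float, float] = (0.20, 0.75)
    par1_xi: tuple[float, float] = (0.49, 0.75)
    bimodal_subtype_fraction: float = 0.17
    borderline_subtype_fraction: float = 0.22
    bimodal_high_xi: tuple[float, float] = (0.30, 0.60)
    borderline_xi: tuple[float, float] = (0.05, 0.16)
    heterogeneous_xi: tuple[float, float] = (0.0, 0.30)
    mean_run_length: float = 6.0        # positional clustering of statuses
    fixed_xi: float | None = None       # force one true %Xi for every X gene
    # cross-set divergence and imprinting
    n_population_specific: int = 4
    n_cell_line_specific: int = 4
    flipped_escape_xi: tuple[float, float] = (0.30, 0.60)
    n_imprinted: int = 1
    # intensities and noise
    log_intensity_mean: float = 8.0
    log_intensity_probe_sd: float = 0.8
    log_intensity_row_sd: float = 0.6
    noise_base_sd: float = 0.02
    noise_amplitude: float = 0.15
    noise_tau: float = 300.0
    # genomic-DNA channel
    gdna_artifact_rate: float = 0.02
    gdna_sd: float = 0.01
    # autosomal background
    autosomal_imbalance_rate: float = 0.10
    autosomal_ai: tuple[float, float] = (0.05, 0.35)
    # ChIP-AI: per-class mean |AI|, anticorrelated with Xi expression
    chip_class_ai: dict = field(default_factory=lambda: {
        ExpressionClass.SUBJECT_LT5.value: 0.30,
        ExpressionClass.SUBJECT_GE5.value: 0.22,
        ExpressionClass.ESCAPE_OUTSIDE_PAR1_RANGE.value: 0.15,
        ExpressionClass.ESCAPE_IN_PAR1_RANGE.value: 0.08,
    })
    chip_ai_sd: float = 0.05
    chip_marks: tuple[str, ...] = ("H3K4me1", "H3K4me3", "H3K27me3")
    chip_promoter_probes: int = 2
    chip_body_probes: int = 80          # ~40x the promoter count
    # geometry
    chrom_length: int = 155_000_000
    par1_end: int = 2_700_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heterozygosity_rate", "frac_high_skew", "frac_moderate_skew",
                     "subject_fraction", "escape_fraction", "gdna_artifact_rate",
                     "autosomal_imbalance_rate", "subject_zero_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_x_genes <= self.n_par1_genes:
            raise ValueError("need more X genes than PAR1 genes")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValueError("probes_per_gene must be an increasing positive range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortTruth:
    """Ground truth for recovery tests: true skews, %Xi, statuses, geometry."""

    females: pd.DataFrame          # sample, sample_set, true_skew
    genes: pd.DataFrame            # indexed by gene: coords, par1, true_status, ...
    status_per_set: pd.DataFrame   # genes x sample sets, true per-set status
    xi_per_female: pd.DataFrame    # genes x females, true per-female %Xi
    probe_map: pd.DataFrame        # probe_id -> gene (AUTO for background)
    artifact_probes: list[str]
    subject_training: list[str]
    escape_training: list[str]
    config: CohortConfig

    def annotation(self) -> pd.DataFrame:
        """BED-style annotation frame with strand-resolved TSS/TES."""
        g = self.genes
        ann = pd.DataFrame({
            "chrom": g["chrom"], "start": g["start"], "end": g["end"],
            "gene": g.index, "score": 0, "strand": g["strand"],
            "par1": g["par1"].astype(int),
        })
        minus = ann["strand"] == "-"
        ann["tss"] = np.where(minus, ann["end"], ann["start"])
        ann["tes"] = np.where(minus, ann["start"], ann["end"])
        return ann


def _draw_skews(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.skew_values is not None:
        vals = np.asarray(cfg.skew_values, dtype=float)
        if len(vals) != n:
            raise ValueError(f"skew_values must list {n} females, got {len(vals)}")
        return vals
    u = rng.random(n)
    comp = np.where(u < cfg.frac_high_skew, 0,
                    np.where(u < cfg.frac_high_skew + cfg.frac_moderate_skew, 1, 2))
    betas = (cfg.high_skew_beta, cfg.moderate_skew_beta, cfg.random_skew_beta)
    draws = np.empty(n)
    for k, (a, b) in enumerate(betas):
        mask = comp == k
        draws[mask] = rng.beta(a, b, size=int(mask.sum()))
    return 0.5 + 0.5 * draws


def _status_runs(pools: dict[str, int], mean_run: float,
                 rng: np.random.Generator) -> list[str]:
    """Lay statuses out in geometric-length runs for positional clustering."""
    remaining = dict(pools)
    order: list[str] = []
    while any(v > 0 for v in remaining.values()):
        labels = [s for s, v in remaining.items() if v > 0]
        weights = np.array([remaining[s] for s in labels], dtype=float)
        status = rng.choice(labels, p=weights / weights.sum())
        run = min(1 + rng.geometric(1.0 / mean_run), remaining[status])
        order.extend([status] * run)
        remaining[status] -= run
    return order


def _build_genes(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_nonpar = cfg.n_x_genes - cfg.n_par1_genes
    # PAR1 genes packed into the PAR1 interval, the rest evenly spaced beyond it
    par1_starts = np.linspace(50_000, cfg.par1_end - 150_000, cfg.n_par1_genes).astype(int)
    par1_len = rng.integers(5_000, 100_000, cfg.n_par1_genes)
    spacing = (cfg.chrom_length - 3_000_000) / n_nonpar
    jitter = rng.integers(0, max(int(spacing * 0.2), 1), n_nonpar)
    nonpar_starts = (3_000_000 + spacing * np.arange(n_nonpar)).astype(int) + jitter
    nonpar_len = rng.integers(5_000, min(200_000, int(spacing * 0.6)), n_nonpar)

    n_subject = int(round(cfg.subject_fraction * n_nonpar))
    n_escape = int(round(cfg.escape_fraction * n_nonpar))
    n_variable = n_nonpar - n_subject - n_escape
    order = _status_runs(
        {GenicStatus.SUBJECT.value: n_subject,
         GenicStatus.ESCAPE.value: n_escape,
         GenicStatus.VARIABLE_ESCAPE.value: n_variable},
        cfg.mean_run_length, rng,
    )

    names = [f"XG{i:04d}" for i in range(cfg.n_x_genes)]
    starts = np.concatenate([par1_starts, nonpar_starts])
    lengths = np.concatenate([par1_len, nonpar_len])
    statuses = [GenicStatus.ESCAPE.value] * cfg.n_par1_genes + order
    genes = pd.DataFrame({
        "gene": names,
        "chrom": "chrX",
        "start": starts,
        "end": starts + lengths,
        "strand": rng.choice(["+", "-"], cfg.n_x_genes),
        "par1": [1] * cfg.n_par1_genes + [0] * n_nonpar,
        "true_status": statuses,
    }).set_index("gene", drop=False)

    base_xi = np.zeros(cfg.n_x_genes)
    subtype = np.array([""] * cfg.n_x_genes, dtype=object)
    for i, (name, rec) in enumerate(genes.iterrows()):
        if rec["par1"]:
            base_xi[i] = rng.uniform(*cfg.par1_xi)
        elif rec["true_status"] == GenicStatus.SUBJECT.value:
            base_xi[i] = (0.0 if rng.random() < cfg.subject_zero_fraction
                          else rng.uniform(*cfg.subject_low_xi))
        elif rec["true_status"] == GenicStatus.ESCAPE.value:
            base_xi[i] = rng.uniform(*cfg.escape_xi)
        else:
            p_border = cfg.borderline_subtype_fraction
            p_bimodal = cfg.bimodal_subtype_fraction
            u = rng.random()
            subtype[i] = (VariableSubtype.BIMODAL.value if u < p_bimodal
                          else VariableSubtype.BORDERLINE.value if u < p_bimodal + p_border
                          else VariableSubtype.HETEROGENEOUS.value)
            base_xi[i] = np.nan  # drawn per female
    genes["base_xi"] = base_xi
    genes["subtype"] = subtype
    genes["divergence"] = ""
    genes["imprinted"] = False
    if cfg.fixed_xi is not None:
        genes["base_xi"] = float(cfg.fixed_xi)
        genes["subtype"] = ""
        genes["true_status"] = (GenicStatus.SUBJECT.value if cfg.fixed_xi < 0.10
                                else GenicStatus.ESCAPE.value)
    return genes


def _pick_training_and_special(genes: pd.DataFrame, cfg: CohortConfig,
                               rng: np.random.Generator):
    subject_pool = genes.index[genes["true_status"] == GenicStatus.SUBJECT.value]
    zero = [g for g in subject_pool if genes.loc[g, "base_xi"] == 0.0]
    low = [g for g in subject_pool if genes.loc[g, "base_xi"] > 0.0]
    want = min(cfg.n_subject_training, len(subject_pool))
    subject_training = list(rng.permutation(zero))[:want]
    if len(subject_training) < want:
        subject_training += list(rng.permutation(low))[: want - len(subject_training)]
    subject_training = sorted(subject_training)

    escape_pool = genes.index[genes["true_status"] == GenicStatus.ESCAPE.value]
    par1 = [g for g in escape_pool if genes.loc[g, "par1"] == 1]
    nonpar = [g for g in escape_pool if genes.loc[g, "par1"] == 0]
    want_e = min(cfg.n_escape_training, len(escape_pool))
    escape_training = list(par1)[:want_e]
    if len(escape_training) < want_e:
        escape_training += list(rng.permutation(nonpar))[: want_e - len(escape_training)]
    escape_training = sorted(escape_training)

    taken = set(subject_training) | set(escape_training)
    flippable = [g for g in genes.index
                 if genes.loc[g, "true_status"] in
                 (GenicStatus.SUBJECT.value, GenicStatus.ESCAPE.value)
                 and g not in taken and genes.loc[g, "par1"] == 0]
    flippable = list(rng.permutation(flippable))
    n_pop, n_cell = cfg.n_population_specific, cfg.n_cell_line_specific
    pop_specific = flippable[:n_pop]
    cell_specific = flippable[n_pop:n_pop + n_cell]
    imprint_pool = [g for g in flippable[n_pop + n_cell:]
                    if genes.loc[g, "true_status"] == GenicStatus.SUBJECT.value]
    imprinted = imprint_pool[: cfg.n_imprinted]
    return subject_training, escape_training, pop_specific, cell_specific, imprinted


def simulate_cohort(config: CohortConfig | None = None) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate an expression probe table plus its ground truth."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n_sets = len(cfg.sample_sets)
    n_females = n_sets * cfg.n_females_per_set

    samples = [f"{sset}_F{i:02d}" for sset in cfg.sample_sets
               for i in range(cfg.n_females_per_set)]
    set_of_female = np.repeat(np.arange(n_sets), cfg.n_females_per_set)
    skews = _draw_skews(cfg, rng, n_females)
    females = pd.DataFrame({
        "sample": samples,
        "sample_set": [cfg.sample_sets[k] for k in set_of_female],
        "true_skew": skews,
    })

    genes = _build_genes(cfg, rng)
    (subject_training, escape_training, pop_specific,
     cell_specific, imprinted) = _pick_training_and_special(genes, cfg, rng)
    genes.loc[pop_specific, "divergence"] = "population_specific"
    genes.loc[cell_specific, "divergence"] = "cell_line_specific"
    genes.loc[imprinted, "imprinted"] = True

    # per-set base xi and per-set true status; divergent genes flip in one set
    n_genes = len(genes)
    xi_per_set = np.tile(genes["base_xi"].to_numpy(dtype=float)[:, None], (1, n_sets))
    status_per_set = np.tile(
        genes["true_status"].to_numpy(dtype=object)[:, None], (1, n_sets)
    )
    gene_pos = {g: i for i, g in enumerate(genes.index)}

    def flip(gene: str, set_idx: int) -> None:
        i = gene_pos[gene]
        if genes.loc[gene, "true_status"] == GenicStatus.SUBJECT.value:
            xi_per_set[i, set_idx] = rng.uniform(*cfg.flipped_escape_xi)
            status_per_set[i, set_idx] = GenicStatus.ESCAPE.value
        else:
            xi_per_set[i, set_idx] = 0.0
            status_per_set[i, set_idx] = GenicStatus.SUBJECT.value
        genes.loc[gene, "true_status"] = GenicStatus.VARIABLE_ESCAPE.value

    for g in pop_specific:
        flip(g, 1 if n_sets > 1 else 0)    # second same-cell-type set differs
    for g in cell_specific:
        flip(g, n_sets - 1)                # the other-cell-type set differs

    # per-female true xi: set value, or per-female draws for variable genes
    xi_female = xi_per_set[:, set_of_female].copy()
    for g in genes.index[genes["subtype"] != ""]:
        i = gene_pos[g]
        st = genes.loc[g, "subtype"]
        if st == VariableSubtype.BIMODAL.value:
            high = rng.uniform(*cfg.bimodal_high_xi, size=n_females)
            xi_female[i] = np.where(rng.random(n_females) < 0.5, 0.0, high)
        elif st == VariableSubtype.BORDERLINE.value:
            xi_female[i] = rng.uniform(*cfg.borderline_xi, size=n_females)
        else:
            xi_female[i] = rng.uniform(*cfg.heterogeneous_xi, size=n_females)
    for g in imprinted:
        xi_female[gene_pos[g]] = 0.0

    # probes: X genes then the autosomal background
    lo, hi = cfg.probes_per_gene
    probes_per_gene = rng.integers(lo, hi + 1, n_genes)
    for g in imprinted:            # the planted imprinted signal must be observable
        probes_per_gene[gene_pos[g]] = hi
    x_probe_gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
    x_probe_ids, x_probe_pos = [], []
    for i, g in enumerate(genes.index):
        k = probes_per_gene[i]
        pos = np.sort(rng.integers(genes.loc[g, "start"], genes.loc[g, "end"], k))
        for j in range(k):
            x_probe_ids.append(f"p_{g}_{j}")
            x_probe_pos.append(int(pos[j]))
    n_x_probes = len(x_probe_ids)

    auto_ids = [f"pa{i:05d}" for i in range(cfg.n_autosomal_probes)]
    auto_chrom = rng.choice(_AUTOSOMES, cfg.n_autosomal_probes)
    auto_pos = rng.integers(100_000, 240_000_000, cfg.n_autosomal_probes)
    auto_imbalanced = rng.random(cfg.n_autosomal_probes) < cfg.autosomal_imbalance_rate
    auto_ai = np.where(auto_imbalanced, rng.uniform(*cfg.autosomal_ai,
                                                    cfg.n_autosomal_probes), 0.0)

    probe_id = np.array(x_probe_ids + auto_ids, dtype=object)
    probe_gene = np.array(
        [genes.index[i] for i in x_probe_gene_idx] + [AUTOSOME_MARKER] * cfg.n_autosomal_probes,
        dtype=object,
    )
    probe_chrom = np.array(["chrX"] * n_x_probes + list(auto_chrom), dtype=object)
    probe_pos = np.array(x_probe_pos + list(auto_pos), dtype=int)
    n_probes = len(probe_id)
    artifact = rng.random(n_probes) < cfg.gdna_artifact_rate
    mu_probe = rng.normal(cfg.log_intensity_mean, cfg.log_intensity_probe_sd, n_probes)

    # row grid: probe-major x female
    P, F = n_probes, n_females
    r_probe = np.repeat(np.arange(P), F)
    r_female = np.tile(np.arange(F), P)
    informative = rng.random(P * F) < cfg.heterozygosity_rate
    intensity = np.exp(rng.normal(mu_probe[r_probe], cfg.log_intensity_row_sd))
    noise_sd = cfg.noise_base_sd + cfg.noise_amplitude * np.exp(-intensity / cfg.noise_tau)

    skew_row = skews[r_female]
    is_x = r_probe < n_x_probes
    gene_idx_row = np.where(is_x, x_probe_gene_idx[np.minimum(r_probe, n_x_probes - 1)], -1)

    f_true = np.empty(P * F)
    # heterozygous X probes: forward model at (female skew, per-female gene xi)
    xi_row = np.where(is_x, xi_female[gene_idx_row, r_female], 0.0)
    f_model = (skew_row + xi_row * (1.0 - skew_row)) / (1.0 + xi_row)
    flip_orient = rng.random(P * F) < 0.5
    f_x = np.where(flip_orient, 1.0 - f_model, f_model)
    # imprinted genes: mono-allelic regardless of skew
    imprint_rows = np.zeros(P * F, dtype=bool)
    if imprinted:
        imprint_idx = {gene_pos[g] for g in imprinted}
        imprint_rows = is_x & np.isin(gene_idx_row, list(imprint_idx))
    f_x = np.where(imprint_rows, (rng.random(P * F) < 0.5).astype(float), f_x)
    # heterozygous autosomal probes: balanced, or a fixed cis imbalance
    auto_ai_row = np.where(~is_x, auto_ai[np.maximum(r_probe - n_x_probes, 0)], 0.0)
    auto_sign = np.where(rng.random(P * F) < 0.5, 1.0, -1.0)
    f_auto = 0.5 + auto_sign * auto_ai_row
    f_het = np.where(is_x, f_x, f_auto)
    # homozygous probes: one allele only
    f_hom = (rng.random(P * F) < 0.5).astype(float)
    f_true = np.where(informative, f_het, f_hom)

    frac_expr = np.clip(f_true + rng.normal(0.0, 1.0, P * F) * noise_sd, 0.0, 1.0)

    # genomic-DNA channel: ~0.5 for heterozygotes, artifact probes skewed
    gdna_het = np.clip(rng.normal(0.5, cfg.gdna_sd, P * F), 0.0, 1.0)
    art_val = rng.uniform(0.75, 0.92, P * F)
    art_side = rng.random(P) < 0.5          # artifact direction fixed per probe
    gdna_art = np.where(art_side[r_probe], art_val, 1.0 - art_val)
    gdna_het = np.where(artifact[r_probe], gdna_art, gdna_het)
    gdna_hom = np.clip(np.round(f_true) + rng.normal(0.0, cfg.gdna_sd, P * F), 0.0, 1.0)
    frac_gdna = np.where(informative, gdna_het, gdna_hom)

    probes = pd.DataFrame({
        "probe_id": probe_id[r_probe],
        "gene": probe_gene[r_probe],
        "chrom": probe_chrom[r_probe],
        "pos": probe_pos[r_probe],
        "sample": np.array(samples, dtype=object)[r_female],
        "sex": "F",
        "sample_set": np.array(females["sample_set"], dtype=object)[r_female],
        "informative": informative.astype(int),
        "intensity": intensity,
        "frac_expr": frac_expr,
        "frac_gdna": frac_gdna,
        "channel": EXPRESSION_CHANNEL,
    })[PROBE_COLUMNS]

    n_informative_x = int(probes[(probes["gene"] != AUTOSOME_MARKER)
                                 & (probes["informative"] == 1)].shape[0])
    if n_informative_x == 0:
        warnings.warn("configuration produced no informative X-linked probes")

    truth = CohortTruth(
        females=females,
        genes=genes,
        status_per_set=pd.DataFrame(status_per_set, index=genes.index,
                                    columns=list(cfg.sample_sets)),
        xi_per_female=pd.DataFrame(xi_female, index=genes.index, columns=samples),
        probe_map=pd.DataFrame({"probe_id": probe_id, "gene": probe_gene}),
        artifact_probes=sorted(probe_id[artifact]),
        subject_training=subject_training,
        escape_training=escape_training,
        config=cfg,
    )
    return probes, truth


def true_expression_classes(truth: CohortTruth) -> pd.Series:
    """Ground-truth expression class per gene (variable/divergent genes excluded)."""
    genes = truth.genes
    par1_xi = genes.loc[genes["par1"] == 1, "base_xi"]
    par1_min = float(par1_xi.min()) if not par1_xi.empty else np.inf
    out = {}
    for g, rec in genes.iterrows():
        if rec["subtype"] or rec["divergence"] or rec["imprinted"]:
            continue
        if rec["true_status"] == GenicStatus.ESCAPE.value:
            out[g] = (ExpressionClass.ESCAPE_IN_PAR1_RANGE.value
                      if rec["par1"] or rec["base_xi"] >= par1_min
                      else ExpressionClass.ESCAPE_OUTSIDE_PAR1_RANGE.value)
        elif rec["true_status"] == GenicStatus.SUBJECT.value:
            out[g] = (ExpressionClass.SUBJECT_GE5.value if rec["base_xi"] >= 0.05
                      else ExpressionClass.SUBJECT_LT5.value)
    return pd.Series(out, name="expression_class")


def simulate_chip(truth: CohortTruth, config: CohortConfig | None = None) -> pd.DataFrame:
    """ChIP-AI probe table: |AI| drawn per expression class, per mark and region.

    Gene bodies receive ``chip_body_probes`` probes against
    ``chip_promoter_probes`` at the promoter (about 40x more), and the
    configured class means decrease from the most silenced class to the
    PAR1-range escapees, giving the anticorrelation with %Xi the class
    comparison is meant to detect.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    classes = true_expression_classes(truth)
    ann = truth.annotation().set_index("gene")
    rows = []
    sset = cfg.sample_sets[0]
    for mark in cfg.chip_marks:
        for gene, cls in classes.items():
            mean_ai = cfg.chip_class_ai[cls]
            rec = ann.loc[gene]
            for region, n_probes in (("promoter", cfg.chip_promoter_probes),
                                     ("gene_body", cfg.chip_body_probes)):
                if region == "promoter":
                    pos = rng.integers(rec["tss"] - 999, rec["tss"] + 999, n_probes)
                else:
                    pos = rng.integers(rec["start"], rec["end"], n_probes)
                ai = np.clip(rng.normal(mean_ai, cfg.chip_ai_sd, n_probes), 0.0, 0.49) \
                    if cfg.chip_ai_sd > 0 else np.full(n_probes, mean_ai)
                sign = np.where(rng.random(n_probes) < 0.5, 1.0, -1.0)
                intensity = np.exp(rng.normal(cfg.log_intensity_mean, 1.0, n_probes))
                for j in range(n_probes):
                    rows.append((
                        f"c_{mark}_{gene}_{region}_{j}", gene, rec["chrom"],
                        int(pos[j]), f"{sset}_CHIP", "F", sset, 1,
                        float(intensity[j]), float(0.5 + sign[j] * ai[j]),
                        0.5, f"chip:{mark}",
                    ))
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


def simulate_decay_probes(n: int, y0: float, plateau: float, tau: float,
                          noise_sd: float = 0.01, seed: int = 0,
                          sample_set: str = "LCL1",
                          intensity_max: float | None = None) -> pd.DataFrame:
    """Uninformative probes whose AI follows a known one-phase decay.

    Used to exercise the Tau QC fit against a known decay constant: the AI
    of each homozygous probe is plateau + (y0 - plateau) exp(-I/tau) plus
    Gaussian noise, encoded as an allele fraction near 1 so that
    min(f, 1 - f) recovers it.
    """
    rng = np.random.default_rng(seed)
    upper = intensity_max if intensity_max is not None else 5.0 * tau
    intensity = rng.uniform(0.0, upper, n)
    ai = plateau + (y0 - plateau) * np.exp(-intensity / tau)
    ai = np.clip(ai + rng.normal(0.0, noise_sd, n), 0.0, 0.5)
    return pd.DataFrame({
        "probe_id": [f"pu{i:05d}" for i in range(n)],
        "gene": AUTOSOME_MARKER,
        "chrom": "chr1",
        "pos": np.arange(n) * 100 + 1_000,
        "sample": "U_F00",
        "sex": "F",
        "sample_set": sample_set,
        "informative": 0,
        "intensity": intensity,
        "frac_expr": 1.0 - ai,
        "frac_gdna": 1.0,
        "channel": EXPRESSION_CHANNEL,
    })[PROBE_COLUMNS]
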