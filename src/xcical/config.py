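"""Pipeline configuration: every numeric decision rule in one place.

Modules read these knobs and never hard-code them, so each threshold exists
exactly once.  Defaults are the values the method was designed around: the
10%-Xi escape cutoff, the 2/9 / 7/9 genic fractions (7-of-9 informative
samples, kept as exact rationals), the 0.7 genomic-DNA ratio with 50%
prevalence, autosomal quantiles 0.90/0.95/0.995, alpha = 0.05, a minimum of
two informative probes per gene and five informative females per sample set,
and a +/-1 kb promoter window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import yaml


@dataclass
class PipelineConfig:
    # status calling
    xi_escape_cutoff: float = 0.10      # %Xi (as fraction of Xa) above which a gene escapes
    genic_subject_max: Fraction = Fraction(2, 9)   # fraction escaping <= 2/9 -> subject
    genic_escape_min: Fraction = Fraction(7, 9)    # fraction escaping >= 7/9 -> escape
    bimodal_fraction: float = 0.75      # min fraction of calls in {E1, S} for bimodal subtype
    subject_class_split: float = 0.05   # mean %Xi splitting subject_ge5 / subject_lt5
    min_probes_per_gene: int = 2
    min_females_genic: int = 1          # min informative females for a genic call
    # probe QC
    gdna_ratio_max: float = 0.7
    gdna_prevalence: float = 0.5
    min_decay_probes: int = 20
    concordance_mode: str = "status"    # "status" (S-vs-E call) or "delta" (|dAI| < concordance_delta)
    concordance_delta: float = 0.1
    # autosomal quantiles
    q_e1: float = 0.90                  # E1:E2 boundary quantile
    q_e2: float = 0.95                  # E2:E3 boundary quantile
    q_mono: float = 0.995               # group-1 / mono-allelic threshold quantile
    # statistics
    alpha: float = 0.05
    grubbs_two_sided: bool = False
    correction: str = "holm"            # multiple-testing correction for ChIP t-tests
    adjacency_df: int | None = None     # default #pairs - 1
    n_permutations: int = 1000
    # cross-sample-set comparison
    min_females_per_set: int = 5
    same_cell_type_sets: tuple[str, str] = ("LCL1", "LCL2")
    other_cell_type_set: str = "FIB"
    # ChIP regions
    promoter_window: int = 1000         # bp either side of the TSS
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.genic_subject_max = Fraction(self.genic_subject_max).limit_denominator(10_000)
        self.genic_escape_min = Fraction(self.genic_escape_min).limit_denominator(10_000)
        for name in ("xi_escape_cutoff", "gdna_ratio_max", "gdna_prevalence",
                     "q_e1", "q_e2", "q_mono", "alpha", "bimodal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.q_e1 <= self.q_e2 <= self.q_mono:
            raise ValueError("autosomal quantiles must be ordered q_e1 <= q_e2 <= q_mono")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genic_subject_max"] = str(self.genic_subject_max)
        d["genic_escape_min"] = str(self.genic_escape_min)
        d["same_cell_type_sets"] = list(self.same_cell_type_sets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("genic_subject_max", "genic_escape_min"):
            if key in d and isinstance(d[key], str):
                d[key] = Fraction(d[key])
        if "same_cell_type_sets" in d:
            d["same_cell_type_sets"] = tuple(d["same_cell_type_sets"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
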