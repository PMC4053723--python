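"""Shared helpers: AI columns, per-gene AI tables, stable hashing."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

AUTOSOME_MARKER = "AUTO"
EXPRESSION_CHANNEL = "expression"


def ai_of_fraction(frac) -> np.ndarray:
    """Allelic imbalance of an allele-1 fraction: |frac - 0.5|."""
    return np.abs(np.asarray(frac, dtype=float) - 0.5)


def uninformative_ai(frac) -> np.ndarray:
    """AI of a homozygous probe: deviation from the clean mono-allelic signal.

    A homozygote carries one allele, so its clean allele-1 fraction is 0 or
    1; any deviation min(f, 1-f) reflects hybridization noise, which is what
    the intensity-decay QC fit models.
    """
    f = np.asarray(frac, dtype=float)
    return np.minimum(f, 1.0 - f)


def expression_rows(probes: pd.DataFrame) -> pd.DataFrame:
    return probes[probes["channel"] == EXPRESSION_CHANNEL]


def informative_x_rows(probes: pd.DataFrame) -> pd.DataFrame:
    """Informative (heterozygous) expression rows on X-linked genes."""
    expr = expression_rows(probes)
    return expr[(expr["informative"] == 1) & (expr["gene"] != AUTOSOME_MARKER)]


def gene_ai_table(probes: pd.DataFrame, min_probes: int = 2) -> pd.DataFrame:
    """Per-(sample, gene) mean probe AI over informative X-linked probes.

    Returns a frame with columns sample, sample_set, gene, n_probes, ai,
    restricted to genes with at least ``min_probes`` informative probes in
    that sample (the minimum the calling rules require).
    """
    rows = informative_x_rows(probes)
    if rows.empty:
        return pd.DataFrame(columns=["sample", "sample_set", "gene", "n_probes", "ai"])
    rows = rows.assign(_ai=ai_of_fraction(rows["frac_expr"]))
    agg = (
        rows.groupby(["sample", "sample_set", "gene"], sort=True)["_ai"]
        .agg(n_probes="size", ai="mean")
        .reset_index()
    )
    return agg[agg["n_probes"] >= min_probes].reset_index(drop=True)


def autosomal_ai_values(probes: pd.DataFrame) -> pd.DataFrame:
    """Informative autosomal expression rows with an ``ai`` column."""
    expr = expression_rows(probes)
    rows = expr[(expr["informative"] == 1) & (expr["gene"] == AUTOSOME_MARKER)]
    return rows.assign(ai=ai_of_fraction(rows["frac_expr"]))


def stable_hash(obj) -> str:
    """Deterministic short hash of a JSON-serialisable object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
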