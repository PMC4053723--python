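"""Readers and writers for the probe-table, annotation and gene-list formats.

One tab-separated probe-table schema serves the expression, genomic-DNA and
ChIP channels via the ``channel`` tag (``expression`` or ``chip:<mark>``),
avoiding three near-identical formats.  Gene annotation is BED6 plus a PAR1
flag column, 0-based half-open, with TSS/TES resolved by strand.  Training
gene sets are plain-text, one id per line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PROBE_COLUMNS = [
    "probe_id", "gene", "chrom", "pos", "sample", "sex", "sample_set",
    "informative", "intensity", "frac_expr", "frac_gdna", "channel",
]

_FRACTION_COLUMNS = ("frac_expr", "frac_gdna")

ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene", "score", "strand", "par1"]


class ProbeTableError(ValueError):
    """Raised when a probe table violates its schema."""


def _first_bad_row(mask: pd.Series) -> int:
    # 1-based data row number (header is row 0)
    return int(np.flatnonzero(mask.to_numpy())[0]) + 1


def validate_probe_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ProbeTableError(f"probe table is missing columns: {missing}")
    df = df[PROBE_COLUMNS].copy()
    for col in _FRACTION_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 1)
        if bad.any():
            raise ProbeTableError(
                f"column {col!r} out of [0, 1] at row {_first_bad_row(bad)}"
            )
        df[col] = vals.astype(float)
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.isna() | (intensity < 0)
    if bad.any():
        raise ProbeTableError(f"negative or non-numeric intensity at row {_first_bad_row(bad)}")
    df["intensity"] = intensity.astype(float)
    df["informative"] = df["informative"].astype(int)
    if not df["informative"].isin((0, 1)).all():
        raise ProbeTableError("informative flag must be 0 or 1")
    df["pos"] = df["pos"].astype(int)
    dup = df.duplicated(subset=["probe_id", "sample", "channel"])
    if dup.any():
        raise ProbeTableError(
            f"duplicate (probe_id, sample, channel) at row {_first_bad_row(dup)}"
        )
    return df


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return validate_probe_table(df)


def write_probe_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    write_table(df[PROBE_COLUMNS], path, header_comment)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write any result table as TSV with an optional ``#`` header comment.

    Float formatting is fixed so identical inputs produce byte-identical
    files.
    """
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read BED6+1 gene annotation (chrom start end gene score strand par1).

    Coordinates are 0-based half-open.  Returns a frame indexed by gene id
    with ``tss``/``tes`` resolved by strand: for a plus-strand gene
    [start, end) the TSS is ``start`` and the TES ``end``; for minus strand
    the TSS is ``end`` and the TES ``start``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=ANNOTATION_COLUMNS, dtype={"chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        gene = df.loc[bad, "gene"].iloc[0]
        raise ValueError(f"gene {gene!r}: start must be < end (0-based half-open)")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in annotation")
    if not df["strand"].isin(("+", "-")).all():
        raise ValueError("strand must be '+' or '-'")
    df["par1"] = df["par1"].astype(int)
    minus = df["strand"] == "-"
    df["tss"] = np.where(minus, df["end"], df["start"])
    df["tes"] = np.where(minus, df["start"], df["end"])
    return df.set_index("gene", drop=False)


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    cols = annotation.reset_index(drop=True)[ANNOTATION_COLUMNS]
    cols.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
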