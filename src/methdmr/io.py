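"""Readers and writers for the plain-text formats the pipeline touches.

Beta matrices and probe manifests travel as TSV, sample sheets as CSV.
Called regions are exported twice: a BED file (0-based half-open, with
the Sidak-corrected p-value next to the region name) and a richer
annotation table with one row per region.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    FormatError,
    ProbeManifest,
    ReferencePanel,
    SampleSheet,
)


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(";") if part.strip()]


def _join_multi(values: Iterable[str]) -> str:
    return ";".join(values)


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV (first column probe_id, header row)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("no samples")
    probe_col = df.columns[0]
    if df[probe_col].duplicated().any():
        dups = df[probe_col][df[probe_col].duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids: {dups}")
    df = df.set_index(probe_col)
    df.index.name = "probe_id"
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric beta value at probe {probe!r}, sample {col!r}"
            )
        df[col] = coerced
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ["probe_id", "chrom", "pos", "genes", "gene_region",
                  "island_relation", "snp_overlap", "sex_chrom"]


def read_manifest(path) -> ProbeManifest:
    """Read a BED-like manifest TSV with semicolon-separated multi-fields."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dups = df["probe_id"][df["probe_id"].duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids in manifest: {dups}")
    df = df.set_index("probe_id")
    df["genes"] = df["genes"].apply(_split_multi)
    df["gene_region"] = df["gene_region"].apply(_split_multi)
    df["snp_overlap"] = df["snp_overlap"].astype(int).astype(bool)
    df["sex_chrom"] = df["sex_chrom"].astype(int).astype(bool)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.table.copy()
    df["genes"] = df["genes"].apply(_join_multi)
    df["gene_region"] = df["gene_region"].apply(_join_multi)
    df["snp_overlap"] = df["snp_overlap"].astype(int)
    df["sex_chrom"] = df["sex_chrom"].astype(int)
    df.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path, age_range=(18.0, 59.0)) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids")
    df = df.set_index("sample_id")
    return SampleSheet(df, age_range=age_range)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def read_reference_panel(path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReferencePanel(df)


def write_reference_panel(panel: ReferencePanel, path) -> None:
    panel.mean_betas.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# DMR export
# ---------------------------------------------------------------------------

DMR_TABLE_COLUMNS = [
    "dmr_id", "chrom", "start", "end", "dmr_length", "n_cpgs",
    "p_region", "p_sidak", "mean_beta", "mean_beta_difference",
    "largest_beta_difference", "direction", "genes", "gene_regions",
    "island_relations",
]


def write_dmrs(dmrs, bed_path, table_path) -> None:
    """Write called regions as BED plus an annotation table.

    BED coordinates are 0-based half-open ([start-1, end) for internal
    1-based inclusive regions) with the Sidak-corrected p in column 5.
    The table reports the length as ``end - start``, matching the usual
    printed convention for array DMRs.
    """
    dmrs = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    for d in dmrs:
        if d.start < 1 or d.end < 1:
            raise FormatError(f"negative or zero coordinate in region {d.chrom}:{d.start}-{d.end}")
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tsidak_p\n")
        for i, d in enumerate(dmrs, start=1):
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\tDMR{i}\t{d.p_sidak:.6g}\n")
    rows = []
    for i, d in enumerate(dmrs, start=1):
        rows.append({
            "dmr_id": f"DMR{i}",
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "dmr_length": d.end - d.start,
            "n_cpgs": d.n_probes,
            "p_region": d.p_region,
            "p_sidak": d.p_sidak,
            "mean_beta": d.mean_beta,
            "mean_beta_difference": d.mean_diff,
            "largest_beta_difference": d.largest_diff,
            "direction": d.direction,
            "genes": _join_multi(d.genes),
            "gene_regions": _join_multi(d.gene_regions),
            "island_relations": _join_multi(d.island_relations),
        })
    pd.DataFrame(rows, columns=DMR_TABLE_COLUMNS).to_csv(table_path, sep="\t", index=False)
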