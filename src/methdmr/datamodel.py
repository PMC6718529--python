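"""Core data containers and transforms shared across the pipeline.

The central measurement object is a beta-value matrix: per-CpG methylation
fractions in [0, 1] for probes (rows) across samples (columns).  Probe
annotation follows EPIC-array conventions: genomic coordinate, associated
gene symbols, gene-region features (TSS1500 ... 3'UTR) and the probe's
relation to the nearest CpG island.  All genomic coordinates held in these
containers are 1-based inclusive; conversion to 0-based half-open happens
only at BED export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PipelineError):
    """Malformed or invariant-violating input data."""


class ParameterError(PipelineError):
    """Invalid argument or configuration value."""


GENE_REGION_VOCAB = frozenset(
    {"TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR"}
)
ISLAND_RELATION_VOCAB = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)
SEX_VOCAB = frozenset({"F", "M"})

#: Samples whose group label differs from this are treated as cases.
CONTROL_GROUP = "control"


# ---------------------------------------------------------------------------
# beta / M-value transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = 1e-6):
    """log2 logit of a methylation fraction, clipped away from {0, 1}.

    Parameters
    ----------
    beta : array-like or float
        Methylation fraction(s) in [0, 1].
    epsilon : float
        Clipping bound in (0, 0.5); values are clipped to [eps, 1-eps]
        before the logit so the transform never produces infinities.
    """
    if not 0.0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m, epsilon: float = 1e-6):
    """Inverse of :func:`beta_to_m` on the clipped range [eps, 1-eps]."""
    if not 0.0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    x = np.exp2(np.asarray(m, dtype=float))
    out = x / (1.0 + x)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _first_offender(mask: np.ndarray, index, columns) -> str:
    i, j = np.argwhere(mask)[0]
    return f"probe {index[i]!r}, sample {columns[j]!r}"


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[1] == 0:
            raise FormatError("no samples")
        if df.shape[0] == 0:
            raise FormatError("no probes")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        try:
            arr = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric beta value: {exc}") from exc
        if np.isnan(arr).any():
            raise FormatError(
                "missing beta value at " + _first_offender(np.isnan(arr), df.index, df.columns)
            )
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            raise FormatError(
                "beta value outside [0, 1] at "
                + _first_offender(bad, df.index, df.columns)
            )
        self.values = df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, probe_ids) -> "BetaMatrix":
        """Subset to the given probes, in the given order."""
        probe_ids = list(probe_ids)
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise FormatError(f"probes absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values.loc[probe_ids])

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy())


@dataclass
class ProbeManifest:
    """Per-probe genomic coordinates and annotation.

    ``table`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (1-based int), ``genes`` (list of symbols, possibly empty),
    ``gene_region`` (list of labels from the gene-region vocabulary),
    ``island_relation`` (single label), ``snp_overlap`` and ``sex_chrom``
    (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"chrom", "pos", "genes", "gene_region", "island_relation",
                    "snp_overlap", "sex_chrom"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids in manifest: {dups}")
        pos = df["pos"].to_numpy()
        if (pos < 1).any():
            raise FormatError("probe position < 1 in manifest")
        bad_rel = set(df["island_relation"]) - ISLAND_RELATION_VOCAB
        if bad_rel:
            raise FormatError(f"unknown island_relation label(s): {sorted(bad_rel)}")
        for pid, regions in df["gene_region"].items():
            bad = set(regions) - GENE_REGION_VOCAB
            if bad:
                raise FormatError(f"unknown gene_region label(s) {sorted(bad)} for probe {pid!r}")
        df["snp_overlap"] = df["snp_overlap"].astype(bool)
        df["sex_chrom"] = df["sex_chrom"].astype(bool)
        df["pos"] = df["pos"].astype(int)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def sort_genomic(self) -> "ProbeManifest":
        """Stable sort by (chrom, pos) with probe_id as the tie-break."""
        df = self.table.copy()
        df["_pid"] = df.index
        df = df.sort_values(["chrom", "pos", "_pid"], kind="mergesort").drop(columns="_pid")
        return ProbeManifest(df)

    def restrict(self, probe_ids) -> "ProbeManifest":
        probe_ids = list(probe_ids)
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise FormatError(f"probes absent from manifest: {missing[:10]}")
        return ProbeManifest(self.table.loc[probe_ids].copy())


@dataclass
class SampleSheet:
    """Sample metadata: group label, age (years), sex, optional pair id.

    Any group label other than :data:`CONTROL_GROUP` marks a case sample;
    cohorts with several case groups (e.g. distinct mutant genotypes) are
    analysed one case group at a time against the shared controls.
    """

    table: pd.DataFrame
    age_range: tuple[float, float] = (18.0, 59.0)

    def __post_init__(self) -> None:
        df = self.table
        required = {"group", "age", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        bad_sex = set(df["sex"]) - SEX_VOCAB
        if bad_sex:
            raise FormatError(f"unknown sex label(s): {sorted(bad_sex)}")
        age = df["age"].to_numpy(dtype=float)
        lo, hi = self.age_range
        if (age <= 0).any() or (age < lo).any() or (age > hi).any():
            raise FormatError(
                f"age outside declared range [{lo}, {hi}]"
            )
        df["age"] = age

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def is_case(self) -> np.ndarray:
        return (self.table["group"] != CONTROL_GROUP).to_numpy()

    def restrict(self, sample_ids) -> "SampleSheet":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise FormatError(f"samples absent from sheet: {missing[:10]}")
        return SampleSheet(self.table.loc[sample_ids].copy(), age_range=self.age_range)


@dataclass
class ReferencePanel:
    """Reference methylation profiles of leukocyte types at panel CpGs.

    ``mean_betas`` holds one column per cell type and one row per
    cell-type-informative probe; entries are reference methylation
    fractions in [0, 1].  The panel must have at least as many probes as
    cell types and full column rank, otherwise constrained deconvolution
    is ill-posed.
    """

    mean_betas: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.mean_betas.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise FormatError("reference panel values must lie in [0, 1]")
        n_probes, n_types = arr.shape
        if n_probes < n_types:
            raise FormatError(
                f"panel has fewer probes ({n_probes}) than cell types ({n_types})"
            )
        if np.linalg.matrix_rank(arr) < n_types:
            raise FormatError("reference panel is rank deficient")

    @property
    def celltype_names(self) -> list[str]:
        return list(self.mean_betas.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.mean_betas.index)
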