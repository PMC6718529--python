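"""Probe filtering, quantile normalization and variable-site selection.

These steps precede all inference: probes flagged as SNP-overlapping or
on sex chromosomes are removed, samples are quantile-normalized so every
sample shares the same marginal distribution of beta values, and
ordination works on the most variable sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, FormatError, ParameterError, ProbeManifest


def filter_probes(
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    drop_snp: bool = True,
    drop_sex: bool = True,
) -> BetaMatrix:
    """Remove SNP-overlapping and/or sex-chromosome probes, keeping order."""
    missing = [p for p in matrix.probe_ids if p not in manifest.table.index]
    if missing:
        raise FormatError(f"probes absent from manifest: {missing[:10]}")
    ann = manifest.table.loc[matrix.probe_ids]
    keep = np.ones(matrix.n_probes, dtype=bool)
    if drop_snp:
        keep &= ~ann["snp_overlap"].to_numpy()
    if drop_sex:
        keep &= ~ann["sex_chrom"].to_numpy()
    if not keep.any():
        raise FormatError("all probes removed by filtering; need at least one")
    return BetaMatrix(matrix.values.loc[keep])


def quantile_normalize(matrix: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the mean of the sorted sample vectors.

    After normalization each sample's sorted values equal the across-
    sample mean of sorted values; tied values within a sample receive the
    mean of the reference values at their tied ranks.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    if matrix.n_probes < 2:
        raise ParameterError("quantile normalization needs at least 2 probes")
    vals = matrix.values.to_numpy()
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over tie groups
        ties = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(out, index=matrix.values.index,
                                   columns=matrix.values.columns))


def select_most_variable(matrix: BetaMatrix, k: int) -> BetaMatrix:
    """Top-k probes by across-sample variance of beta, in input (genomic) order.

    Ranking is by descending variance with probe_id ascending as the
    tie-break; the selected probes are returned in their original row
    order.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    if k > matrix.n_probes:
        raise ParameterError(f"k={k} exceeds number of probes ({matrix.n_probes})")
    var = matrix.values.var(axis=1, ddof=1).to_numpy()
    ranking = pd.DataFrame({"var": var, "probe_id": matrix.probe_ids})
    ranking = ranking.sort_values(["var", "probe_id"], ascending=[False, True],
                                  kind="mergesort")
    chosen = set(ranking["probe_id"].iloc[:k])
    keep = [p for p in matrix.probe_ids if p in chosen]
    return BetaMatrix(matrix.values.loc[keep])
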