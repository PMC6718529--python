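"""Correspondence analysis (CA) of non-negative tables.

CA ordinates the rows and columns of a contingency-like table in the
chi-square metric.  With grand total n, correspondence matrix P = table/n,
row masses r and column masses c, the standardized residual matrix is

    S = diag(r)^(-1/2) (P - r c^T) diag(c)^(-1/2)

whose singular value decomposition S = U Sigma V^T yields principal
coordinates  diag(r)^(-1/2) U Sigma  for rows and
diag(c)^(-1/2) V Sigma  for columns.  The squared singular values are the
per-axis inertias; their sum (the total inertia) equals the Pearson
chi-square statistic of the table divided by the grand total.

Used twice in the pipeline: ordination of samples on the most variable
CpG sites, and derivation of the two cell-composition covariate scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FormatError, ParameterError


@dataclass
class CAResult:
    row_coords: pd.DataFrame      # rows x axes, principal coordinates
    col_coords: pd.DataFrame      # columns x axes, principal coordinates
    inertia_fractions: np.ndarray  # per retained axis, fraction of total
    total_inertia: float           # chi-square / grand total
    singular_values: np.ndarray


def correspondence_analysis(table, n_axes: int = 2) -> CAResult:
    """CA of a non-negative table with deterministic axis signs.

    Axis signs are fixed so that the coordinate of largest magnitude
    (over rows and columns jointly) on each axis is positive, removing
    the SVD sign ambiguity.
    """
    if n_axes < 1:
        raise ParameterError("n_axes must be >= 1")
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        arr = np.asarray(table, dtype=float)
        df = pd.DataFrame(arr)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(f"negative entry at row {df.index[i]!r}, column {df.columns[j]!r}")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise FormatError(f"all-zero row: {df.index[np.argmax(row_sums == 0)]!r}")
    if (col_sums == 0).any():
        raise FormatError(f"all-zero column: {df.columns[np.argmax(col_sums == 0)]!r}")

    n = arr.sum()
    P = arr / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(arr.shape) - 1
    k = min(n_axes, max(max_axes, 1))
    sv_k = sv[:k]
    total_inertia = float((sv ** 2).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        row = (U[:, :k] * sv_k) / np.sqrt(r)[:, None]
        col = (Vt.T[:, :k] * sv_k) / np.sqrt(c)[:, None]
    # degenerate (independence) tables: coordinates are numerically ~0
    if total_inertia > 0:
        fractions = (sv_k ** 2) / total_inertia
    else:
        fractions = np.zeros(k)

    for a in range(k):
        stacked = np.concatenate([row[:, a], col[:, a]])
        if stacked[np.argmax(np.abs(stacked))] < 0:
            row[:, a] *= -1
            col[:, a] *= -1

    axes = [f"axis{a + 1}" for a in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(row, index=df.index, columns=axes),
        col_coords=pd.DataFrame(col, index=df.columns, columns=axes),
        inertia_fractions=fractions,
        total_inertia=total_inertia,
        singular_values=sv_k.copy(),
    )


def plot_sample_map(result: CAResult, groups: pd.Series, path) -> None:
    """Scatter of column (sample) coordinates on axes 1-2, coloured by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.col_coords
    fig, ax = plt.subplots(figsize=(5, 5))
    for g in pd.unique(groups):
        mask = (groups.loc[coords.index] == g).to_numpy()
        sub = coords.loc[mask]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g), s=25)
    pct = result.inertia_fractions * 100
    ax.set_xlabel(f"axis 1 ({pct[0]:.1f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"axis 2 ({pct[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_coordinates(result: CAResult, path) -> None:
    result.col_coords.to_csv(path, sep="\t", index_label="sample_id")
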