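"""Reference-based blood cell-type deconvolution and covariate scores.

Cell composition is a major confounder in whole-blood methylation
studies: group differences in leukocyte proportions masquerade as CpG
methylation differences.  Each sample's proportions are estimated by
constrained least squares against a reference panel of cell-type-
informative CpGs, and the first two axes of a correspondence analysis on
the estimated composition table serve as per-sample covariates in the
site-wise linear model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datamodel import BetaMatrix, FormatError, ParameterError, ReferencePanel
from .correspondence import correspondence_analysis


def estimate_cell_composition(
    matrix: BetaMatrix,
    panel: ReferencePanel,
    tol: float = 1e-12,
) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate per-sample cell-type proportions on the unit simplex.

    For each sample, minimizes ``||y - R w||^2`` subject to ``w >= 0`` and
    ``sum(w) = 1`` (sequential quadratic programming on the simplex).
    Returns a samples x cell-types DataFrame of proportions and the
    per-sample residual norm.
    """
    missing = [p for p in panel.probe_ids if p not in matrix.values.index]
    if missing:
        raise FormatError(f"panel probes absent from matrix: {missing[:10]}")
    R = panel.mean_betas.to_numpy(dtype=float)
    Y = matrix.values.loc[panel.probe_ids].to_numpy(dtype=float)
    n_types = R.shape[1]
    RtR = R.T @ R

    x0 = np.full(n_types, 1.0 / n_types)
    bounds = [(0.0, 1.0)] * n_types
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                    "jac": lambda w: np.ones_like(w)}]

    props = np.empty((Y.shape[1], n_types))
    resid = np.empty(Y.shape[1])
    for s in range(Y.shape[1]):
        y = Y[:, s]
        Rty = R.T @ y
        yty = y @ y

        def objective(w):
            return yty - 2.0 * (Rty @ w) + w @ RtR @ w

        def gradient(w):
            return 2.0 * (RtR @ w - Rty)

        res = minimize(objective, x0, jac=gradient, bounds=bounds,
                       constraints=constraints, method="SLSQP",
                       options={"maxiter": 500, "ftol": tol})
        w = np.clip(res.x, 0.0, None)
        w = w / w.sum()
        props[s] = w
        resid[s] = float(np.linalg.norm(y - R @ w))
    props_df = pd.DataFrame(props, index=matrix.sample_ids,
                            columns=panel.celltype_names)
    return props_df, pd.Series(resid, index=matrix.sample_ids, name="residual_norm")


def composition_covariate_scores(proportions: pd.DataFrame) -> pd.DataFrame:
    """Row principal coordinates (axes 1-2) of a CA on the composition table.

    Samples are rows, cell types columns.  Cell types estimated at zero
    in every sample are dropped before the analysis (all-zero columns
    are undefined in CA); a composition table with no variation yields
    zero scores for every sample.
    """
    if proportions.shape[0] < 3:
        raise ParameterError("need at least 3 samples for covariate scores")
    table = proportions.copy()
    zero_cols = table.columns[(table == 0).all(axis=0)]
    if len(zero_cols):
        warnings.warn(f"dropping cell types estimated zero everywhere: {list(zero_cols)}")
        table = table.drop(columns=zero_cols)
    if table.shape[1] < 3:
        raise ParameterError("need at least 3 non-degenerate cell types")
    result = correspondence_analysis(table, n_axes=2)
    scores = result.row_coords.copy()
    scores.columns = ["cc1", "cc2"][: scores.shape[1]]
    if "cc2" not in scores.columns:
        scores["cc2"] = 0.0
    # near-zero inertia: treat coordinates as exactly zero
    if result.total_inertia < 1e-24:
        scores.loc[:, :] = 0.0
    return scores
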