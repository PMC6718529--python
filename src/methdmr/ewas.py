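"""Site-wise linear modelling of methylation with covariate adjustment.

Each CpG's beta value is regressed on a disease-group indicator plus
covariates (age in years, sex, and two cell-composition scores).  The
group coefficient is the case-minus-control methylation difference on
the beta scale, so a positive effect means hypermethylation in cases.
Per-probe residual variances can be shrunk toward a common prior by
empirical-Bayes moderation (scaled inverse-chi-square prior with degrees
of freedom d0 and scale s0^2 estimated by moment matching on log s^2),
which stabilizes the t statistics of small cohorts.  Benjamini-Hochberg
adjustment across probes yields q-values; an age-by-group interaction
fit asks whether cases drift with age at a different rate than controls,
as opposed to carrying a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import BetaMatrix, CONTROL_GROUP, ParameterError, SampleSheet

SITE_RESULT_COLUMNS = ["effect", "se", "stat", "df", "p", "q"]


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 degrees of freedom (may be inf), scale s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ParameterError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ParameterError("s0_sq must be positive")


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    sheet: SampleSheet,
    scores: pd.DataFrame | None = None,
    terms: tuple[str, ...] | None = None,
    interaction: bool = False,
    case_group: str | None = None,
) -> pd.DataFrame:
    """Build a full-rank design matrix from the sample sheet.

    Default terms: intercept, group (0=control, 1=case), age, sex, and
    cc1/cc2 when composition ``scores`` are provided.  ``interaction``
    appends a group x age product column named ``group:age``.  With a
    multi-group cohort, ``case_group`` restricts the case indicator to
    one group (other case groups should be excluded from the sheet
    beforehand).
    """
    df = sheet.table
    if terms is None:
        terms = ["intercept", "group", "age", "sex"]
        if scores is not None:
            terms += ["cc1", "cc2"]
    cols = {}
    for term in terms:
        if term == "intercept":
            cols[term] = np.ones(len(df))
        elif term == "group":
            if case_group is None:
                cols[term] = (df["group"] != CONTROL_GROUP).astype(float).to_numpy()
            else:
                cols[term] = (df["group"] == case_group).astype(float).to_numpy()
        elif term == "age":
            cols[term] = df["age"].to_numpy(dtype=float)
        elif term == "sex":
            cols[term] = (df["sex"] == "M").astype(float).to_numpy()
        elif term in ("cc1", "cc2"):
            if scores is None:
                raise ParameterError(f"term {term!r} requires composition scores")
            cols[term] = scores.loc[df.index, term].to_numpy(dtype=float)
        else:
            raise ParameterError(f"unknown design term: {term!r}")
    design = pd.DataFrame(cols, index=df.index)
    if interaction:
        if "group" not in design.columns or "age" not in design.columns:
            raise ParameterError("interaction requires both 'group' and 'age' terms")
        design["group:age"] = design["group"] * design["age"]
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ParameterError(
            f"design matrix is rank deficient ({rank} < {design.shape[1]}); "
            "remove a collinear or constant term (e.g. sex in a single-sex cohort)"
        )
    return design


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * abs(x):
            break
    return float(x)


def moderate_variances(
    s_sq: np.ndarray, d: float
) -> tuple[ModerationParams, np.ndarray]:
    """Shrink per-probe residual variances toward an estimated prior.

    The prior (d0, s0^2) is estimated by moment matching on log s^2:
    ``trigamma(d0/2) = var(log s^2) - trigamma(d/2)`` solved by monotone
    root finding (d0 = inf when the right-hand side is non-positive,
    i.e. the observed spread is no wider than sampling noise), then s0^2
    from the mean of log s^2.  The moderated variance is the precision-
    weighted blend ``(d0 s0^2 + d s^2) / (d0 + d)``.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if d < 1:
        raise ParameterError("residual degrees of freedom must be >= 1")
    if (s_sq < 0).any():
        raise ParameterError("negative residual variance")
    positive = s_sq[s_sq > 0]
    if positive.size < 2:
        raise ParameterError("need at least 2 positive variances for moderation")
    logs = np.log(positive)
    mean_log = logs.mean()
    var_log = logs.var(ddof=1)
    if var_log < 1e-12:
        # (numerically) identical variances: the prior is that common value
        # and moderation is a no-op
        s0_sq = float(np.exp(mean_log))
        return ModerationParams(d0=np.inf, s0_sq=s0_sq), s_sq.copy()
    rhs = var_log - _trigamma(d / 2.0)
    if rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(mean_log - special.digamma(d / 2.0) + np.log(d / 2.0)))
        moderated = np.full_like(s_sq, s0_sq)
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = float(np.exp(
            mean_log
            - special.digamma(d / 2.0) + np.log(d / 2.0)
            + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        ))
        moderated = (d0 * s0_sq + d * s_sq) / (d0 + d)
    return ModerationParams(d0=d0, s0_sq=s0_sq), moderated


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# site-wise fits
# ---------------------------------------------------------------------------

def fit_sitewise(
    matrix: BetaMatrix,
    design: pd.DataFrame,
    effect_term: str = "group",
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-probe OLS of beta on the design; returns one row per probe.

    Columns: effect (coefficient of ``effect_term``), se, stat
    (moderated t when ``moderate``), df (residual plus prior), p
    (two-sided), q (BH across all probes).  Probes with zero residual
    variance after moderation are reported with p = 1 (degenerate).
    """
    if effect_term not in design.columns:
        raise ParameterError(f"effect term {effect_term!r} not in design")
    X = design.loc[matrix.sample_ids].to_numpy(dtype=float)
    n, k = X.shape
    df_res = n - k
    if df_res < 1:
        raise ParameterError(f"zero residual degrees of freedom (n={n}, k={k})")
    Y = matrix.values.to_numpy(dtype=float)

    XtX_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ XtX_inv            # probes x k
    resid = Y - coefs @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s_sq = rss / df_res

    j = list(design.columns).index(effect_term)
    vjj = XtX_inv[j, j]
    effect = coefs[:, j]

    if moderate:
        params, s_sq_used = moderate_variances(s_sq, df_res)
        df_total = df_res + params.d0
    else:
        s_sq_used = s_sq
        df_total = float(df_res)

    se = np.sqrt(s_sq_used * vjj)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(stat), df_total)
    p = np.where(se > 0, p, 1.0)
    q = bh_adjust(p)

    return pd.DataFrame(
        {"effect": effect, "se": se, "stat": stat,
         "df": np.full(len(effect), df_total), "p": p, "q": q},
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )


def fit_interaction(
    matrix: BetaMatrix,
    design: pd.DataFrame,
    moderate: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Test the group x age coefficient per probe.

    Requires a design containing a ``group:age`` column and age variance
    within both groups (otherwise the slope difference is
    unidentifiable).  Returns the per-probe results and the count of
    probes with q < 0.05.
    """
    if "group:age" not in design.columns:
        raise ParameterError("design lacks 'group:age' interaction column")
    group = design["group"].to_numpy()
    age = design["age"].to_numpy()
    for g in (0.0, 1.0):
        ages_g = age[group == g]
        if len(ages_g) == 0 or np.var(ages_g) == 0:
            raise ParameterError(
                "age variance is zero within a group; slope difference unidentifiable"
            )
    results = fit_sitewise(matrix, design, effect_term="group:age",
                           moderate=moderate)
    n_significant = int((results["q"] < 0.05).sum())
    return results, n_significant


def age_slopes(
    matrix: BetaMatrix,
    design: pd.DataFrame,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-probe age slope, reported in percentage points per year."""
    results = fit_sitewise(matrix, design, effect_term="age", moderate=moderate)
    results = results.copy()
    results["slope_pp_per_year"] = results["effect"] * 100.0
    results["se_pp_per_year"] = results["se"] * 100.0
    return results
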