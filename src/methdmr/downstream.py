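"""Contingency statistics, set overlaps, gene-set enrichment, and the
repeat-element group comparison.

Fold enrichment of a 2x2 table is observed over expected under
independence: with cells a (in both sets), b (set 1 only), c (set 2
only), d (neither), ``fold = a / (row1_total * col1_total / n)``.
Two-sided Fisher p-values follow the minimum-likelihood convention (sum
of hypergeometric probabilities of all tables with fixed margins no more
likely than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import CONTROL_GROUP, FormatError, ParameterError, SampleSheet
from .ewas import bh_adjust


@dataclass
class EnrichmentTable:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fold_enrichment: float
    p: float
    q: float | None = None
    label: str | None = None


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     label: str | None = None) -> EnrichmentTable:
    """Two-sided Fisher exact test with odds ratio and fold enrichment."""
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ParameterError("counts must be non-negative")
    if sum(counts) == 0:
        raise ParameterError("all-zero contingency table")
    n = a + b + c + d
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    expected = (a + b) * (a + c) / n
    fold = a / expected if expected > 0 else np.inf
    return EnrichmentTable(a=a, b=b, c=c, d=d, odds_ratio=float(odds),
                           fold_enrichment=float(fold), p=float(p), label=label)


def overlap_sets(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact counts of every disjoint Venn region of 2-3 named sets.

    Keys are sorted tuples of the set names an element belongs to; the
    counts sum to the size of the union.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ParameterError("overlap_sets supports 2 or 3 sets")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set.union(set(), *(set(named_sets[n])
                                         for n in names if n not in combo))
            regions[tuple(sorted(combo))] = len(inside - outside)
    return regions


def gene_set_enrichment(
    hit_genes: set,
    annotation: dict[str, set],
    background: set,
) -> pd.DataFrame:
    """Fisher enrichment of each term's gene set among the hits, BH-adjusted.

    Hits must be a subset of the background; each term's genes are
    intersected with the background before building the 2x2 table
    (hit-and-term, hit-only, term-only, neither).
    """
    if not background:
        raise ParameterError("empty background gene set")
    hits = set(hit_genes) & set(background)
    if set(hit_genes) - set(background):
        raise ParameterError("hit genes must be a subset of the background")
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & set(background)
        a = len(hits & term_genes)
        b = len(hits - term_genes)
        c = len(term_genes - hits)
        d = len(background) - a - b - c
        table = fisher_exact_2x2(a, b, c, d, label=term)
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": table.odds_ratio,
                     "fold_enrichment": table.fold_enrichment, "p": table.p})
    df = pd.DataFrame(rows).set_index("term")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p")


def repeat_group_comparison(
    table: pd.DataFrame,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Per-family group means/SEs and an age-adjusted group p-value.

    ``table`` holds per-sample mean methylation percentages (samples x
    repeat families).  For each family and each case group, methylation
    is modelled as ``y ~ group + age`` over that group's samples plus
    the controls, and the group coefficient's p-value reported.
    """
    if not table.index.equals(pd.Index(sheet.sample_ids)):
        table = table.loc[sheet.sample_ids]
    groups = sheet.groups
    case_groups = [g for g in pd.unique(groups) if g != CONTROL_GROUP]
    if CONTROL_GROUP not in set(groups):
        raise FormatError("sample sheet has no control group")
    rows = []
    for fam in table.columns:
        y_all = table[fam]
        for cg in case_groups:
            keep = groups.isin([CONTROL_GROUP, cg])
            sub_sheet = sheet.table.loc[keep]
            y = y_all.loc[keep.index[keep]]
            for side, label in ((CONTROL_GROUP, "control"), (cg, "case")):
                vals = y[sub_sheet["group"] == side]
                if len(vals) < 2:
                    raise ParameterError(
                        f"family {fam!r}: group {side!r} has a single sample, SE undefined"
                    )
            X = pd.DataFrame({
                "intercept": 1.0,
                "group": (sub_sheet["group"] == cg).astype(float),
                "age": sub_sheet["age"].astype(float),
            })
            fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            p_group = float(fit.pvalues[1])
            ctrl = y[sub_sheet["group"] == CONTROL_GROUP]
            case = y[sub_sheet["group"] == cg]
            rows.append({
                "family": fam, "case_group": cg,
                "n_control": len(ctrl), "mean_control": float(ctrl.mean()),
                "se_control": float(ctrl.std(ddof=1) / np.sqrt(len(ctrl))),
                "n_case": len(case), "mean_case": float(case.mean()),
                "se_case": float(case.std(ddof=1) / np.sqrt(len(case))),
                "p_group_age_adjusted": p_group,
            })
    return pd.DataFrame(rows)
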