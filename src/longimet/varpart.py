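"""Variance decomposition of per-sample responses by sequential ANOVA.

Each response (an analyte, or any per-sample score) is regressed on a
declared, ordered list of predictor terms; sequential (Type-I) sums of
squares are computed, summed within user-defined components (genetic,
clinical, lifestyle, design, ...), and reported as fractions of the total
sum of squares together with component-level F-test p-values.  Fractions of
correlated predictors depend on the declared order; the order is therefore
recorded in the output and an ``order_dependent`` flag is set when
predictors are non-orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["VariancePartition", "partition_variance"]


@dataclass
class VariancePartition:
    response: str
    fractions: dict  # component -> fraction of total SS (includes "residual")
    pvalues: dict  # component -> ANOVA F-test p
    term_ss: dict  # term -> sequential SS
    order: list
    grouping: dict
    n_used: int
    n_dropped: int
    order_dependent: bool = False
    notes: list = field(default_factory=list)


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col, drop_first=True)
        return dummies.to_numpy(float)
    return col.to_numpy(float)[:, None]


def partition_variance(
    response: pd.Series,
    design: pd.DataFrame,
    grouping: dict,
    order: list | None = None,
) -> VariancePartition:
    """Sequential (Type-I) ANOVA variance partition of one response.

    ``grouping`` maps each term (column of ``design``) to a component name;
    ``order`` fixes the sequence in which terms enter (defaults to the
    design's column order).  Categorical/object columns are dummy-coded.
    Rows with any missing value are dropped (complete cases).  Sequential SS
    are computed as R^2 increments of nested OLS fits times the total SS,
    which is the classical Type-I decomposition.
    """
    if order is None:
        order = list(design.columns)
    unknown = [t for t in order if t not in design.columns]
    if unknown:
        raise ValueError(f"order references unknown terms: {unknown}")
    missing_grp = [t for t in order if t not in grouping]
    if missing_grp:
        raise ValueError(f"terms without component grouping: {missing_grp}")

    df = pd.concat([response.rename("__y__"), design[order]], axis=1)
    n_before = len(df)
    df = df.dropna()
    n = len(df)
    y = df["__y__"].to_numpy(float)
    y = y - y.mean()
    ss_total = float(y @ y)
    if ss_total <= 0:
        raise ValueError("response has zero variance")

    blocks = [_term_matrix(df, t) for t in order]
    n_params = 1 + sum(b.shape[1] for b in blocks)
    X_full = np.column_stack([np.ones(n)] + blocks)
    rank = np.linalg.matrix_rank(X_full)
    if rank < n_params:
        # identify the first term that adds no rank
        cum = np.ones((n, 1))
        for t, b in zip(order, blocks):
            r0 = np.linalg.matrix_rank(cum)
            cum = np.column_stack([cum, b])
            if np.linalg.matrix_rank(cum) < r0 + b.shape[1]:
                raise ValueError(f"design is rank deficient at term {t!r}")
        raise ValueError("design is rank deficient")

    term_ss: dict[str, float] = {}
    term_df: dict[str, int] = {}
    X = np.ones((n, 1))
    rss_prev = ss_total
    for t, b in zip(order, blocks):
        X = np.column_stack([X, b])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        term_ss[t] = rss_prev - rss
        term_df[t] = b.shape[1]
        rss_prev = rss
    ss_resid = rss_prev
    df_resid = n - n_params

    # orthogonality check: correlations between distinct term blocks
    order_dependent = False
    cen = [b - b.mean(axis=0) for b in blocks]
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if np.abs(cen[i].T @ cen[j]).max() > 1e-8 * n:
                order_dependent = True

    fractions: dict[str, float] = {}
    pvalues: dict[str, float] = {}
    comp_ss: dict[str, float] = {}
    comp_df: dict[str, int] = {}
    for t in order:
        comp = grouping[t]
        comp_ss[comp] = comp_ss.get(comp, 0.0) + term_ss[t]
        comp_df[comp] = comp_df.get(comp, 0) + term_df[t]
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    for comp, ss in comp_ss.items():
        fractions[comp] = max(ss, 0.0) / ss_total
        if df_resid > 0 and ms_resid > 0:
            F = (ss / comp_df[comp]) / ms_resid
            pvalues[comp] = float(stats.f.sf(F, comp_df[comp], df_resid))
        else:
            pvalues[comp] = 0.0 if ss > 0 else np.nan
    fractions["residual"] = ss_resid / ss_total

    return VariancePartition(
        response=str(response.name),
        fractions=fractions,
        pvalues=pvalues,
        term_ss=term_ss,
        order=list(order),
        grouping={t: grouping[t] for t in order},
        n_used=n,
        n_dropped=n_before - n,
        order_dependent=order_dependent,
    )
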