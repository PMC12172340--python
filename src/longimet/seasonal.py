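"""Inter-/intra-individual variability and harmonic seasonal mixed models.

The seasonal model per analyte is the cosinor linear mixed model

    abundance ~ sin(2*pi*month/12) + cos(2*pi*month/12) + sex + BMI + age
                + (1 | subject)

fitted by REML.  The seasonal amplitude is sqrt(beta_sin^2 + beta_cos^2),
which is invariant to the phase of the underlying oscillation, and
seasonality is tested by the joint 2-df Wald F test of (beta_sin, beta_cos)
with containment-style denominator degrees of freedom.  Analytes significant
after Benjamini-Hochberg correction are clustered on their z-scaled monthly
mean profiles with Ward ("ward.D2") linkage, and clusters are functionally
characterised with two-sided Fisher exact enrichment over an annotation-term
universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "compute_cv",
    "fit_seasonal",
    "bh_adjust",
    "cluster_seasonal",
    "enrich_terms",
    "SeasonalClusters",
]


def compute_cv(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    summary: str = "median",
) -> pd.DataFrame:
    """Inter- and intra-individual coefficients of variation per analyte.

    inter_cv: within each visit, CV (sd/|mean|) across participants, then
    summarised over visits.  intra_cv: within each participant, CV across
    that participant's visits, then summarised over participants.  Strata
    with fewer than two observations or a near-zero mean are excluded from
    the summary.  ``ratio = inter_cv / intra_cv`` is NaN when intra_cv is 0.

    The CVs are computed on whatever scale the matrix is on (the analysis
    pipeline uses log2 abundances).
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    agg = np.nanmedian if summary == "median" else np.nanmean
    cohort = cohort.loc[matrix.index]
    if cohort["subject"].nunique() < 2 or cohort["visit"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 visits")

    def _strata_cv(groups) -> np.ndarray:
        out = []
        for _, g in groups:
            x = g.to_numpy(float)
            x = x[~np.isnan(x)]
            if x.size < 2:
                continue
            m = x.mean()
            if abs(m) < 1e-12:
                continue
            out.append(x.std(ddof=1) / abs(m))
        return np.array(out) if out else np.array([np.nan])

    rows = []
    visit_groups = list(matrix.groupby(cohort["visit"].to_numpy()))
    subj_groups = list(matrix.groupby(cohort["subject"].to_numpy()))
    for analyte in matrix.columns:
        inter = agg(_strata_cv((k, g[analyte]) for k, g in visit_groups))
        intra = agg(_strata_cv((k, g[analyte]) for k, g in subj_groups))
        ratio = inter / intra if (np.isfinite(intra) and intra > 0) else np.nan
        rows.append({"analyte": analyte, "inter_cv": inter, "intra_cv": intra, "ratio": ratio})
    return pd.DataFrame(rows).set_index("analyte")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _seasonal_design(cohort: pd.DataFrame) -> pd.DataFrame:
    ang = 2.0 * np.pi * cohort["month"].to_numpy(float) / 12.0
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "sin_m": np.sin(ang),
            "cos_m": np.cos(ang),
            "sex": cohort["sex"].to_numpy(float),
            "bmi": cohort["bmi"].to_numpy(float),
            "age": cohort["age"].to_numpy(float),
        },
        index=cohort.index,
    )


def _joint_season_test(beta: np.ndarray, cov: np.ndarray, ddf: float) -> float:
    """Two-sided p of the joint Wald F test of the sin/cos coefficients."""
    try:
        w = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        return np.nan
    if w < 0 or not np.isfinite(w):
        return np.nan
    return float(stats.f.sf(w / 2.0, 2, max(ddf, 3.0)))


def fit_seasonal(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    fdr_alpha: float = 0.05,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Fit the cosinor mixed model to every analyte.

    Returns a table indexed by analyte with beta_sin, beta_cos, amplitude,
    covariate effects, variance components, the joint 2-df seasonality
    p-value, its BH-adjusted q across the successfully fitted family, and a
    status flag ("ok", "ols_fallback" when the mixed fit failed or was
    degenerate and a fixed-effects fit was used, "skipped" when too few
    observations).  Skipped/failed analytes are excluded from the FDR family.
    """
    cohort = cohort.loc[matrix.index]
    if cohort["month"].nunique() < 3:
        raise ValueError("need >= 3 distinct sampling months")
    X = _seasonal_design(cohort)
    subj = cohort["subject"].to_numpy()

    rows = []
    for analyte in matrix.columns:
        y = matrix[analyte].to_numpy(float)
        obs = ~np.isnan(y)
        rec = dict.fromkeys(
            [
                "beta_sin", "beta_cos", "amplitude", "beta_sex", "beta_bmi",
                "beta_age", "sigma_subject2", "sigma_resid2", "p_season",
            ],
            np.nan,
        )
        rec["analyte"] = analyte
        rec["n_obs"] = int(obs.sum())
        if obs.sum() < min_obs:
            rec["status"] = "skipped"
            rows.append(rec)
            continue
        Xo = X.to_numpy(float)[obs]
        yo = y[obs]
        so = subj[obs]
        n_subj = len(np.unique(so))
        ddf = obs.sum() - n_subj - Xo.shape[1] + 1
        fitted = False
        if n_subj < obs.sum():  # repeated measures present
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = MixedLM(yo, Xo, groups=so).fit(reml=True)
                fe = np.asarray(res.fe_params)
                cov = np.asarray(res.cov_params())[1:3, 1:3]
                if np.all(np.isfinite(fe)) and np.all(np.isfinite(cov)):
                    rec.update(
                        beta_sin=fe[1], beta_cos=fe[2], beta_sex=fe[3],
                        beta_bmi=fe[4], beta_age=fe[5],
                        sigma_subject2=float(np.squeeze(res.cov_re)),
                        sigma_resid2=float(res.scale),
                    )
                    rec["p_season"] = _joint_season_test(fe[1:3], cov, ddf)
                    rec["status"] = "ok"
                    fitted = np.isfinite(rec["p_season"])
            except (np.linalg.LinAlgError, ValueError):
                fitted = False
        if not fitted:
            # degenerate or singular mixed fit: plain OLS on the fixed effects
            beta, res_ss, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
            dof = obs.sum() - rank
            s2 = float(res_ss[0]) / dof if (res_ss.size and dof > 0) else 0.0
            XtXi = np.linalg.pinv(Xo.T @ Xo)
            cov = s2 * XtXi[1:3, 1:3]
            rec.update(
                beta_sin=beta[1], beta_cos=beta[2], beta_sex=beta[3],
                beta_bmi=beta[4], beta_age=beta[5],
                sigma_subject2=0.0, sigma_resid2=s2,
            )
            if s2 <= 1e-14:
                # perfect fit: seasonal terms either exactly zero or exact
                amp2 = beta[1] ** 2 + beta[2] ** 2
                rec["p_season"] = 1.0 if amp2 <= 1e-20 else 0.0
            else:
                rec["p_season"] = _joint_season_test(beta[1:3], cov, dof)
            rec["status"] = "ols_fallback"
        rec["amplitude"] = float(np.hypot(rec["beta_sin"], rec["beta_cos"]))
        rows.append(rec)

    table = pd.DataFrame(rows).set_index("analyte")
    table["q_season"] = bh_adjust(table["p_season"].to_numpy())
    table["significant"] = table["q_season"] < fdr_alpha
    return table


@dataclass
class SeasonalClusters:
    assignment: pd.Series  # analyte -> cluster label (significant analytes only)
    monthly_profiles: pd.DataFrame  # analyte x 12 z-scaled monthly means
    cluster_profiles: pd.DataFrame  # cluster x 12 mean profiles
    imputed_months: dict = field(default_factory=dict)  # analyte -> [months]


def _monthly_profile(values: np.ndarray, months: np.ndarray) -> tuple[np.ndarray, list]:
    """Mean per calendar month with circular linear interpolation of gaps."""
    prof = np.full(12, np.nan)
    for m in range(1, 13):
        sel = (months == m) & ~np.isnan(values)
        if sel.any():
            prof[m - 1] = values[sel].mean()
    imputed = [int(m) for m in np.flatnonzero(np.isnan(prof)) + 1]
    if imputed and np.isfinite(prof).any():
        known = np.flatnonzero(np.isfinite(prof))
        for idx in np.flatnonzero(np.isnan(prof)):
            # nearest known months forward and backward around the circle
            dists_f = (known - idx) % 12
            dists_b = (idx - known) % 12
            f = known[np.argmin(dists_f)]
            b = known[np.argmin(dists_b)]
            df_, db_ = dists_f.min(), dists_b.min()
            prof[idx] = (prof[f] * db_ + prof[b] * df_) / (df_ + db_)
    return prof, imputed


def cluster_seasonal(
    fits: pd.DataFrame,
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    n_groups: int,
    fdr_alpha: float = 0.05,
) -> SeasonalClusters:
    """Ward ("ward.D2") clustering of significant analytes' monthly profiles.

    Each significant analyte's 12 calendar-month means are z-scaled and
    clustered on Euclidean distance; the dendrogram is cut at ``n_groups``.
    Months with no samples are filled by circular linear interpolation and
    recorded in ``imputed_months``.
    """
    sig = fits.index[(fits["q_season"] < fdr_alpha).fillna(False)]
    if len(sig) < n_groups:
        raise ValueError(f"only {len(sig)} significant analytes for {n_groups} groups")
    cohort = cohort.loc[matrix.index]
    months = cohort["month"].to_numpy(int)

    profiles = np.zeros((len(sig), 12))
    imputed = {}
    for i, analyte in enumerate(sig):
        prof, imp = _monthly_profile(matrix[analyte].to_numpy(float), months)
        sd = prof.std()
        profiles[i] = (prof - prof.mean()) / sd if sd > 0 else prof - prof.mean()
        if imp:
            imputed[analyte] = imp
    # scipy's "ward" on raw observations implements the ward.D2 criterion
    Z = linkage(profiles, method="ward")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    assignment = pd.Series(labels, index=sig, name="seasonal_cluster")
    prof_df = pd.DataFrame(profiles, index=sig, columns=[f"m{m}" for m in range(1, 13)])
    cluster_prof = prof_df.groupby(assignment).mean()
    return SeasonalClusters(assignment, prof_df, cluster_prof, imputed)


def enrich_terms(
    assignment: pd.Series,
    terms: dict,
    universe: set | list,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of annotation terms per cluster.

    For each (cluster, term): a = members with the term, b = members
    without, c = non-members with, d = non-members without (over the
    universe); odds ratio a*d/(b*c); BH correction across all pairs.
    """
    universe = set(universe)
    members = set(assignment.index)
    if not members <= universe:
        raise ValueError("cluster members must be a subset of the universe")
    all_terms = sorted({t for a in universe for t in terms.get(a, ())})
    rows = []
    for cluster in sorted(assignment.unique()):
        in_c = {a for a in members if assignment[a] == cluster}
        out_c = universe - in_c
        for term in all_terms:
            a = sum(1 for x in in_c if term in terms.get(x, ()))
            b = len(in_c) - a
            c = sum(1 for x in out_c if term in terms.get(x, ()))
            d = len(out_c) - c
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"cluster": cluster, "term": term, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds, "p": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
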