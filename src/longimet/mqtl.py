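"""Metabolite QTL mapping from longitudinal data.

The GWAS phenotype is a per-subject "adjusted level": the subject-block
coefficient of a fixed-effects regression of the metabolite on subject and
visit indicators (equivalently the visit-effect-corrected subject mean).
Associations are ordinary least squares of the adjusted level on genotype
dosage with sex, age and baseline BMI as covariates, vectorised across
variants through Frisch-Waugh-Lovell residualisation (numerically identical
to per-variant multiple regression).

The significance threshold divides the genome-wide 5e-8 by the effective
number of independent metabolites (Li-Ji eigenvalue estimator by default).
Independent mQTLs are obtained by greedy LD pruning (r^2 and window rule)
followed by conditional analysis on the per-metabolite lead variant.
Fixed-effect inverse-variance meta-analysis combines per-cohort summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeData

__all__ = [
    "adjusted_levels",
    "gwas_scan",
    "effective_tests",
    "bonferroni_threshold",
    "ld_prune",
    "conditional_refine",
    "meta_fixed",
    "MetaStat",
]


def adjusted_levels(matrix: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Visit-adjusted per-subject metabolite levels (subjects x metabolites).

    Fits, per metabolite, ``level ~ subject indicators + visit indicators``
    (no global intercept; the first visit is the reference level) on the
    observed samples; the subject coefficients are the adjusted levels.
    Subjects with no observed value for a metabolite get NaN.
    """
    cohort = cohort.loc[matrix.index]
    subjects = pd.Index(pd.unique(cohort["subject"]), name="subject")
    visits = np.sort(cohort["visit"].unique())
    subj_codes = pd.Categorical(cohort["subject"], categories=subjects).codes
    visit_codes = pd.Categorical(cohort["visit"], categories=visits).codes

    n = len(cohort)
    S, V = len(subjects), len(visits)
    D = np.zeros((n, S + V - 1))
    D[np.arange(n), subj_codes] = 1.0
    nz = visit_codes > 0
    D[np.flatnonzero(nz), S + visit_codes[nz] - 1] = 1.0

    Y = matrix.to_numpy(float)
    out = np.full((S, matrix.shape[1]), np.nan)
    cache: dict[bytes, np.ndarray] = {}
    for j in range(matrix.shape[1]):
        obs = ~np.isnan(Y[:, j])
        if not obs.any():
            continue
        key = obs.tobytes()
        if key not in cache:
            cache[key] = np.linalg.pinv(D[obs])
        coef = cache[key] @ Y[obs, j]
        have = np.unique(subj_codes[obs])
        out[have, j] = coef[have]
    return pd.DataFrame(out, index=subjects, columns=matrix.columns)


def _residualize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of columns of A on covariate matrix C (with intercept)."""
    coef, *_ = np.linalg.lstsq(C, A, rcond=None)
    return A - C @ coef


def gwas_scan(
    levels: pd.DataFrame,
    genotypes: GenotypeData,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(variant, metabolite) OLS association scan.

    ``levels`` is subjects x metabolites (the adjusted levels), ``covariates``
    subjects x {sex, age, bmi}.  Returns the long summary table with columns
    variant_id, chrom, pos, metabolite, beta, se, t, p, n.  Constant-dosage
    variants within the analysed subjects are skipped.
    """
    common = levels.index.intersection(genotypes.subjects).intersection(covariates.index)
    if len(common) < 10:
        raise ValueError("fewer than 10 subjects shared across inputs")
    L = levels.loc[common].to_numpy(float)
    G = genotypes.dosage.loc[common].to_numpy(float)
    C = np.column_stack([np.ones(len(common)), covariates.loc[common].to_numpy(float)])
    if np.isnan(C).any():
        raise ValueError("covariates contain missing values")
    info = genotypes.info

    frames = []
    k_cov = C.shape[1]
    complete_geno = not np.isnan(G).any()
    # residualize genotypes once when complete
    if complete_geno:
        Gr_full = _residualize(G, C)
    for j, met in enumerate(levels.columns):
        obs = ~np.isnan(L[:, j])
        n = int(obs.sum())
        if n < k_cov + 2:
            continue
        Co = C[obs]
        y = _residualize(L[obs, j][:, None], Co)[:, 0]
        if complete_geno and n == len(common):
            Gr = Gr_full
        else:
            Go = G[obs]
            keep_rows = ~np.isnan(Go).any(axis=1)
            # per-variant missing dosages are rare in practice; fall back to
            # dropping rows with any missing dosage for this metabolite
            if not keep_rows.all():
                Co = Co[keep_rows]
                y = _residualize(L[obs, j][keep_rows][:, None], Co)[:, 0]
                Go = Go[keep_rows]
                n = int(keep_rows.sum())
            Gr = _residualize(Go, Co)
        gss = np.einsum("ij,ij->j", Gr, Gr)
        ok = gss > 1e-12
        if not ok.any():
            continue
        gty = Gr.T @ y
        beta = np.where(ok, gty / np.where(ok, gss, 1.0), np.nan)
        df = n - k_cov - 1
        rss = y @ y - beta * gty
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / np.where(ok, gss, np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = beta / se
        p = 2.0 * stats.t.sf(np.abs(tval), df)
        sub = pd.DataFrame(
            {
                "variant_id": genotypes.variants[ok],
                "chrom": info["chrom"].to_numpy()[ok],
                "pos": info["pos"].to_numpy()[ok],
                "metabolite": met,
                "beta": beta[ok],
                "se": se[ok],
                "t": tval[ok],
                "p": p[ok],
                "n": n,
            }
        )
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "metabolite", "beta", "se", "t", "p", "n"]
        )
    return pd.concat(frames, ignore_index=True)


def effective_tests(matrix: pd.DataFrame, method: str = "li_ji") -> int:
    """Effective number of independent analytes from the correlation spectrum.

    ``li_ji``: sum over eigenvalues of I(lambda >= 1) + fractional part,
    rounded to the nearest integer and clamped to [1, M].  ``var95``: the
    number of eigenvalues needed to explain 95% of total variance.
    """
    M = matrix.shape[1]
    if M < 2:
        raise ValueError("need >= 2 analytes")
    corr = matrix.corr(min_periods=3).to_numpy(float)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    # the Li-Ji step function is discontinuous at integers; snap eigenvalues
    # within solver precision of an integer so exact-block spectra behave
    near = np.abs(lam - np.round(lam)) < 1e-8
    lam[near] = np.round(lam[near])
    if method == "li_ji":
        m_eff = float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    elif method == "var95":
        lam_sorted = np.sort(lam)[::-1]
        cum = np.cumsum(lam_sorted) / lam_sorted.sum()
        m_eff = float(np.searchsorted(cum, 0.95) + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return int(min(max(round(m_eff), 1), M))


def bonferroni_threshold(alpha_gw: float = 5e-8, m_eff: int = 1) -> float:
    """Genome-wide threshold corrected for the effective number of traits."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    if not (0 < alpha_gw < 1):
        raise ValueError("alpha_gw must be in (0, 1)")
    return alpha_gw / m_eff


def ld_prune(
    stats_table: pd.DataFrame,
    genotypes: GenotypeData,
    r2_max: float = 0.1,
    window_bp: float = 1e6,
) -> pd.DataFrame:
    """Greedy LD pruning of association signals, per metabolite.

    Walking variants by ascending p (ties by chrom, pos), a variant is kept
    unless it lies within ``window_bp`` of an already-kept variant on the
    same chromosome with squared dosage correlation > ``r2_max``.  Adds a
    ``pruned_partners`` column listing what each kept variant removed.
    """
    kept_frames = []
    dos = genotypes.dosage
    for met, sub in stats_table.groupby("metabolite", sort=True):
        sub = sub.sort_values(["p", "chrom", "pos"], kind="stable")
        kept: list[int] = []
        partners: dict[int, list] = {}
        for idx, row in sub.iterrows():
            drop = False
            for kidx in kept:
                krow = sub.loc[kidx]
                if krow["chrom"] != row["chrom"]:
                    continue
                if abs(float(krow["pos"]) - float(row["pos"])) > window_bp:
                    continue
                g1 = dos[krow["variant_id"]].to_numpy(float)
                g2 = dos[row["variant_id"]].to_numpy(float)
                ok = ~(np.isnan(g1) | np.isnan(g2))
                if ok.sum() < 3 or g1[ok].std() == 0 or g2[ok].std() == 0:
                    continue
                r2 = np.corrcoef(g1[ok], g2[ok])[0, 1] ** 2
                if r2 > r2_max:
                    drop = True
                    partners[kidx].append(row["variant_id"])
                    break
            if not drop:
                kept.append(idx)
                partners[idx] = []
        out = sub.loc[kept].copy()
        out["pruned_partners"] = [partners[i] for i in kept]
        kept_frames.append(out)
    if not kept_frames:
        return stats_table.iloc[0:0].assign(pruned_partners=None)
    return pd.concat(kept_frames, ignore_index=True)


def conditional_refine(
    pruned: pd.DataFrame,
    genotypes: GenotypeData,
    levels: pd.DataFrame,
    covariates: pd.DataFrame,
    p_cond_max: float = 0.01,
) -> pd.DataFrame:
    """Conditional analysis on the per-metabolite lead variant.

    For each metabolite with multiple surviving signals, every non-lead
    variant is re-tested in an OLS including the lead variant's dosage as a
    covariate; signals with conditional p >= ``p_cond_max`` (or collinear
    with the lead) are dropped.  Single-signal metabolites pass
    unconditionally with an empty conditional p.
    """
    common = levels.index.intersection(genotypes.subjects).intersection(covariates.index)
    C = np.column_stack([np.ones(len(common)), covariates.loc[common].to_numpy(float)])
    rows = []
    for met, sub in pruned.groupby("metabolite", sort=True):
        sub = sub.sort_values(["p", "chrom", "pos"], kind="stable")
        lead = sub.iloc[0]
        rows.append({**lead.to_dict(), "conditional_p": np.nan, "is_lead": True})
        if len(sub) == 1:
            continue
        y_all = levels.loc[common, met].to_numpy(float)
        g_lead = genotypes.dosage.loc[common, lead["variant_id"]].to_numpy(float)
        for _, row in sub.iloc[1:].iterrows():
            g = genotypes.dosage.loc[common, row["variant_id"]].to_numpy(float)
            obs = ~(np.isnan(y_all) | np.isnan(g) | np.isnan(g_lead))
            X = np.column_stack([g[obs], g_lead[obs], C[obs]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # collinear with lead: not an independent signal
            beta, res_ss, *_ = np.linalg.lstsq(X, y_all[obs], rcond=None)
            df = obs.sum() - X.shape[1]
            if df <= 0 or not res_ss.size:
                continue
            s2 = float(res_ss[0]) / df
            cov = s2 * np.linalg.inv(X.T @ X)
            tval = beta[0] / np.sqrt(cov[0, 0])
            p_cond = 2.0 * stats.t.sf(abs(tval), df)
            if p_cond < p_cond_max:
                rows.append({**row.to_dict(), "conditional_p": p_cond, "is_lead": False})
    return pd.DataFrame(rows)


@dataclass
class MetaStat:
    beta_meta: float
    se_meta: float
    z: float
    p: float
    k_cohorts: int
    cohort_betas: tuple
    cohort_ses: tuple


def meta_fixed(per_cohort: pd.DataFrame | list) -> MetaStat:
    """Inverse-variance fixed-effect meta-analysis of one association.

    Accepts a DataFrame or list of dicts with ``beta`` and ``se`` (and
    optionally ``effect_allele``/``other_allele``, which must then agree
    across cohorts).  Weights are 1/se^2.
    """
    df = pd.DataFrame(per_cohort)
    if df.empty:
        raise ValueError("need >= 1 cohort")
    for col in ("effect_allele", "other_allele"):
        if col in df.columns and df[col].nunique() > 1:
            raise ValueError(f"cohorts disagree on {col}: {sorted(df[col].unique())}")
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    if (se <= 0).any() or np.isnan(se).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaStat(beta_meta, se_meta, float(z), p, len(df), tuple(beta), tuple(se))
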