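"""Protein-metabolite association network with one-sample Mendelian
randomization and betweenness-based node tiering.

The association scan fits, per (protein, metabolite) pair, the linear mixed
model ``metabolite ~ protein + sex + age + BMI`` with crossed random
intercepts for subject and visit, and controls the FDR over the full pair
family by Benjamini-Hochberg.  Causality is probed by one-sample two-stage
least squares (2SLS) using the protein's independent cis-pQTLs as
instruments (variants associated with more than five proteins are excluded
as likely pleiotropic); phenotypes are collapsed to the subject level with
the same visit-adjusted coefficients used for mQTL mapping, since genotypes
are subject-level.

The network integrates LMM-significant pairs (edges), upgrading an edge when
the MR estimate is also FDR-significant.  Nodes are tiered on unnormalized
shortest-path betweenness: Tier 1 above median + 2 MAD, Tier 2 above
median + 1 MAD (raw MAD, no consistency constant; with MAD = 0 the
thresholds collapse onto the median and the strict inequalities still
apply).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .seasonal import bh_adjust

__all__ = [
    "lmm_scan",
    "select_instruments",
    "mr_2sls",
    "MRRecord",
    "build_network",
    "tier_nodes",
    "TierAssignment",
]

_VC_CROSSED = {"subj": "0 + C(subj)", "visit": "0 + C(visit)"}
_VC_SUBJ = {"subj": "0 + C(subj)"}


def _pair_lmm(data: pd.DataFrame, ddf: float) -> dict:
    """Fit y ~ x + sex + age + bmi with crossed subject/visit intercepts.

    The crossed random intercepts use the single-group variance-component
    formulation.  If the fit fails or is degenerate, the visit intercept is
    dropped ("no_visit_re"); as a last resort plain OLS is used
    ("ols_fallback").  The slope p-value is a t-test with containment-style
    denominator df.
    """
    for vc, status in ((_VC_CROSSED, "ok"), (_VC_SUBJ, "no_visit_re")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                mod = MixedLM.from_formula(
                    "y ~ x + sex + age + bmi",
                    groups="g",
                    vc_formula=vc,
                    data=data,
                )
                res = mod.fit(reml=True)
            beta = float(res.fe_params["x"])
            se = float(res.bse_fe["x"])
            if np.isfinite(beta) and np.isfinite(se) and se > 0:
                t = beta / se
                return {
                    "beta": beta,
                    "se": se,
                    "p": float(2.0 * stats.t.sf(abs(t), ddf)),
                    "status": status,
                }
        except (np.linalg.LinAlgError, ValueError):
            continue
    X = np.column_stack(
        [np.ones(len(data)), data[["x", "sex", "age", "bmi"]].to_numpy(float)]
    )
    y = data["y"].to_numpy(float)
    coef, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(y) - rank
    if dof <= 0 or not res_ss.size:
        return {"beta": np.nan, "se": np.nan, "p": np.nan, "status": "failed"}
    s2 = float(res_ss[0]) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    t = coef[1] / se if se > 0 else np.nan
    return {
        "beta": float(coef[1]),
        "se": se,
        "p": float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan,
        "status": "ols_fallback",
    }


def lmm_scan(
    metabolites: pd.DataFrame,
    proteins: pd.DataFrame,
    cohort: pd.DataFrame,
    fdr_alpha: float = 0.05,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Mixed-model association scan over all protein-metabolite pairs.

    Rows of both matrices are (subject, visit) samples shared with the
    cohort table.  Pairs with fewer than ``min_obs`` complete observations,
    or a constant protein, are skipped.  The q column is BH-adjusted over
    the whole scanned family.
    """
    samples = metabolites.index.intersection(proteins.index)
    if len(samples) == 0:
        raise ValueError("metabolite and protein matrices share no samples")
    coh = cohort.loc[samples]
    base = pd.DataFrame(
        {
            "sex": coh["sex"].to_numpy(float),
            "age": coh["age"].to_numpy(float),
            "bmi": coh["bmi"].to_numpy(float),
            "subj": coh["subject"].astype(str).to_numpy(),
            "visit": coh["visit"].astype(str).to_numpy(),
            "g": 1,
        },
        index=samples,
    )
    rows = []
    for prot in proteins.columns:
        x_all = proteins.loc[samples, prot].to_numpy(float)
        for met in metabolites.columns:
            y_all = metabolites.loc[samples, met].to_numpy(float)
            obs = ~(np.isnan(x_all) | np.isnan(y_all))
            n = int(obs.sum())
            if n < min_obs:
                continue
            x = x_all[obs]
            if np.std(x) < 1e-12:
                continue
            data = base.loc[samples[obs]].copy()
            data["x"] = x
            data["y"] = y_all[obs]
            n_subj = data["subj"].nunique()
            n_visit = data["visit"].nunique()
            ddf = max(n - n_subj - n_visit - 3, 3)
            rec = _pair_lmm(data, ddf)
            if rec["status"] == "failed":
                continue
            rows.append({"protein": prot, "metabolite": met, "n": n, **rec})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["sign"] = np.where(out["beta"] >= 0, "+", "-")
        out["significant"] = out["q"] < fdr_alpha
    return out


def select_instruments(
    pqtl_stats: pd.DataFrame,
    p_max: float = 5e-8,
    max_protein_assoc: int = 5,
    genotypes=None,
    r2_max: float = 0.1,
    window_bp: float = 1e6,
) -> dict:
    """Choose independent pQTL instruments per protein.

    ``pqtl_stats`` is a GWAS-style table over proteins (columns variant_id,
    chrom, pos, metabolite-or-protein column named "protein", beta, se, p).
    Variants significant (p < ``p_max``) for more than ``max_protein_assoc``
    proteins are excluded everywhere (pleiotropy guard, strict >).  Remaining
    significant variants are LD-pruned per protein when ``genotypes`` is
    given.  Proteins with no surviving instrument are absent from the map.
    """
    stats_df = pqtl_stats.rename(columns={"protein": "metabolite"})
    sig = stats_df[stats_df["p"] < p_max]
    n_assoc = sig.groupby("variant_id")["metabolite"].nunique()
    pleio = set(n_assoc.index[n_assoc > max_protein_assoc])
    sig = sig[~sig["variant_id"].isin(pleio)]
    if sig.empty:
        return {}
    if genotypes is not None:
        from .mqtl import ld_prune

        sig = ld_prune(sig, genotypes, r2_max=r2_max, window_bp=window_bp)
    return {
        prot: list(sub.sort_values("p", kind="stable")["variant_id"])
        for prot, sub in sig.groupby("metabolite")
    }


@dataclass
class MRRecord:
    protein: str
    metabolite: str
    instruments: list
    theta_hat: float
    se: float
    p: float
    first_stage_F: float
    n: int
    weak_instruments: bool


def mr_2sls(
    metabolite: pd.Series,
    protein: pd.Series,
    instruments: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    protein_name: str = "",
    metabolite_name: str = "",
) -> MRRecord:
    """One-sample two-stage least squares for one protein-metabolite pair.

    All inputs are subject-level (one row per subject).  Stage one regresses
    the protein on instruments plus covariates; stage two regresses the
    metabolite on the fitted protein plus covariates.  The reported standard
    error uses the 2SLS residual (actual exposure, not the fitted one).  The
    first-stage F statistic tests the instruments jointly; F < 10 raises the
    conventional weak-instrument flag.
    """
    idx = metabolite.index.intersection(protein.index).intersection(instruments.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    y = metabolite.loc[idx].to_numpy(float)
    x = protein.loc[idx].to_numpy(float)
    Z = instruments.loc[idx].to_numpy(float)
    W = np.ones((len(idx), 1))
    if covariates is not None:
        W = np.column_stack([W, covariates.loc[idx].to_numpy(float)])
    obs = ~(np.isnan(y) | np.isnan(x) | np.isnan(Z).any(axis=1) | np.isnan(W).any(axis=1))
    y, x, Z, W = y[obs], x[obs], Z[obs], W[obs]
    n = len(y)

    keep = Z.std(axis=0) > 1e-12
    dropped = [c for c, k in zip(instruments.columns, keep) if not k]
    Z = Z[:, keep]
    iv_names = [c for c, k in zip(instruments.columns, keep) if k]
    if Z.shape[1] == 0:
        raise ValueError(
            f"no usable instruments (zero-variance columns dropped: {dropped})"
        )
    k_w, k_z = W.shape[1], Z.shape[1]
    if n < k_w + k_z + 2:
        raise ValueError("too few subjects for 2SLS")

    # stage 1: x ~ W + Z
    WZ = np.column_stack([W, Z])
    g1, rss1_arr, *_ = np.linalg.lstsq(WZ, x, rcond=None)
    xhat = WZ @ g1
    rss_full = float(np.sum((x - xhat) ** 2))
    g0, *_ = np.linalg.lstsq(W, x, rcond=None)
    rss_restr = float(np.sum((x - W @ g0) ** 2))
    df1 = n - k_w - k_z
    F = ((rss_restr - rss_full) / k_z) / (rss_full / df1) if df1 > 0 and rss_full > 0 else np.inf

    # stage 2: y ~ W + xhat, with 2SLS-consistent sigma^2 from the actual x
    X2 = np.column_stack([W, xhat])
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    theta = float(b2[-1])
    resid = y - np.column_stack([W, x]) @ b2
    df2 = n - X2.shape[1]
    sigma2 = float(resid @ resid) / df2
    XtXi = np.linalg.pinv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * XtXi[-1, -1]))
    t = theta / se if se > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t), df2)) if np.isfinite(t) else np.nan
    return MRRecord(
        protein=protein_name or str(protein.name),
        metabolite=metabolite_name or str(metabolite.name),
        instruments=iv_names,
        theta_hat=theta,
        se=se,
        p=p,
        first_stage_F=float(F),
        n=n,
        weak_instruments=bool(F < 10),
    )


def build_network(
    lmm: pd.DataFrame,
    mr: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> nx.Graph:
    """Integrate LMM and MR results into the bipartite association network.

    Every LMM pair with q < ``fdr_alpha`` becomes an edge (kind "lmm"),
    upgraded to "lmm+mr" when the pair's MR q (BH over the MR family) is
    also below ``fdr_alpha``.  MR-significant pairs that are not
    LMM-significant violate the scan hierarchy and are skipped with a
    warning.  Edge weight is -log10(q) of the LMM test.
    """
    G = nx.Graph()
    sig = lmm[lmm["q"] < fdr_alpha]
    mr = mr.copy()
    if len(mr):
        mr["q"] = bh_adjust(mr["p"].to_numpy())
    mr_sig = {
        (r.protein, r.metabolite)
        for r in mr.itertuples()
        if len(mr) and r.q < fdr_alpha
    }
    lmm_pairs = set(zip(sig["protein"], sig["metabolite"]))
    for pair in mr_sig - lmm_pairs:
        warnings.warn(f"MR-significant pair {pair} is not LMM-significant; skipped")
    for row in sig.itertuples():
        pair = (row.protein, row.metabolite)
        q = max(row.q, 1e-300)
        G.add_node(row.protein, kind="protein")
        G.add_node(row.metabolite, kind="metabolite")
        G.add_edge(
            row.protein,
            row.metabolite,
            kind="lmm+mr" if pair in mr_sig else "lmm",
            sign=row.sign,
            weight=float(-np.log10(q)),
        )
    return G


@dataclass
class TierAssignment:
    table: pd.DataFrame  # node, kind, betweenness, tier
    median: float
    mad: float

    def tier(self, node) -> str:
        return self.table.set_index("node").loc[node, "tier"]


def tier_nodes(graph: nx.Graph) -> TierAssignment:
    """Tier nodes by unnormalized shortest-path betweenness.

    Betweenness is computed on the undirected, unweighted graph.  With
    m = median and raw MAD over all nodes pooled: Tier 1 when score >
    m + 2 MAD, Tier 2 when m + 1 MAD < score <= m + 2 MAD, otherwise
    "other".  Graphs with fewer than 3 nodes have all-zero betweenness and
    every node "other".
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_nodes() < 3:
        bc = {v: 0.0 for v in graph.nodes}
    else:
        bc = nx.betweenness_centrality(graph, normalized=False, weight=None)
    scores = np.array(list(bc.values()), dtype=float)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    # strict > with a relative tolerance so that scores exactly on a
    # threshold (up to float accumulation order) never cross it
    tol = 1e-9 * max(1.0, abs(med) + 2 * mad)
    rows = []
    for node, score in bc.items():
        if score > med + 2 * mad + tol:
            tier = "1"
        elif score > med + 1 * mad + tol:
            tier = "2"
        else:
            tier = "other"
        rows.append(
            {
                "node": node,
                "kind": graph.nodes[node].get("kind", ""),
                "betweenness": float(score),
                "tier": tier,
            }
        )
    return TierAssignment(pd.DataFrame(rows), med, mad)
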