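"""Quality control of analyte matrices and genotype dosages.

Analyte filters: drop analytes missing in >= 30% of samples, drop analytes
whose interquartile range varies more than two-fold across the first four
visits, drop duplicated analytes; drop subjects with fewer than four
follow-up visits.  Variant filters: missingness, minor-allele frequency
< 5%, and the exact Hardy-Weinberg equilibrium test at P < 1e-6 (the
enumeration-over-heterozygote-counts test that PLINK applies by default).

Every rule records the exact items it removed in a :class:`QCReport` whose
counts reconcile with the matrix shapes before and after.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import GenotypeData

__all__ = [
    "QCRule",
    "QCReport",
    "log2_transform",
    "filter_analytes",
    "filter_subjects",
    "qc_genotypes",
    "hwe_exact_pvalue",
]


@dataclass
class QCRule:
    name: str
    threshold: object
    removed: list
    n_input: int

    @property
    def n_retained(self) -> int:
        return self.n_input - len(self.removed)


@dataclass
class QCReport:
    rules: list[QCRule] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, threshold, removed, n_input: int) -> None:
        self.rules.append(QCRule(name, threshold, sorted(removed), int(n_input)))

    def removed_items(self) -> set:
        out: set = set()
        for r in self.rules:
            out.update(r.removed)
        return out

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "name": r.name,
                    "threshold": r.threshold,
                    "removed": list(r.removed),
                    "n_input": r.n_input,
                    "n_retained": r.n_retained,
                }
                for r in self.rules
            ],
            "warnings": list(self.warnings),
        }


def log2_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """log2-transform a linear-scale analyte matrix (NaN cells preserved).

    Raises ``ValueError`` listing offending cells if any observed value is
    non-positive, since those have no log.
    """
    vals = raw.to_numpy(float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [(str(raw.index[r]), str(raw.columns[c])) for r, c in zip(rows[:10], cols[:10])]
        raise ValueError(
            f"{bad.sum()} non-positive values cannot be log2-transformed; "
            f"first offending cells: {cells}"
        )
    return pd.DataFrame(np.log2(vals), index=raw.index, columns=raw.columns)


def _iqr(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return np.nan
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def filter_analytes(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    max_missing_frac: float = 0.30,
    iqr_ratio_max: float = 2.0,
    drop_duplicates: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the three analyte-level filters, in order.

    1. detection: missing fraction >= ``max_missing_frac`` (inclusive);
    2. stability: max/min interquartile range across the first four visits
       > ``iqr_ratio_max`` (an IQR of zero against a positive one counts as
       unstable; an all-zero-IQR analyte is constant and retained);
    3. duplicates: identical column names, then identical value vectors
       (NaNs compared as equal), keeping the first occurrence.
    """
    report = QCReport()
    cohort = cohort.loc[matrix.index]

    miss_frac = matrix.isna().mean(axis=0)
    removed_miss = list(matrix.columns[miss_frac >= max_missing_frac])
    report.add("missing_fraction", max_missing_frac, removed_miss, matrix.shape[1])
    mat = matrix.drop(columns=removed_miss)

    visits = sorted(cohort["visit"].unique())[:4]
    if len(visits) < 2:
        report.warnings.append(
            "fewer than 2 visits: IQR-ratio rule skipped"
        )
        removed_iqr: list = []
        report.add("iqr_ratio", iqr_ratio_max, removed_iqr, mat.shape[1])
    else:
        groups = [mat.loc[cohort["visit"].isin([v]).to_numpy()] for v in visits]
        removed_iqr = []
        for col in mat.columns:
            iqrs = np.array([_iqr(g[col].to_numpy(float)) for g in groups])
            iqrs = iqrs[~np.isnan(iqrs)]
            if iqrs.size < 2:
                continue
            mx, mn = iqrs.max(), iqrs.min()
            if mx == 0.0:
                continue  # constant analyte: ratio defined as 1
            ratio = np.inf if mn == 0.0 else mx / mn
            if ratio > iqr_ratio_max:
                removed_iqr.append(col)
        report.add("iqr_ratio", iqr_ratio_max, removed_iqr, mat.shape[1])
        mat = mat.drop(columns=removed_iqr)

    if drop_duplicates:
        dup_id = mat.columns[mat.columns.duplicated()]
        removed_dup = list(dup_id)
        if len(removed_dup):
            mat = mat.loc[:, ~mat.columns.duplicated()]
        seen: dict[bytes, str] = {}
        dup_vec = []
        for col in mat.columns:
            key = np.nan_to_num(mat[col].to_numpy(float), nan=np.inf).tobytes()
            if key in seen:
                dup_vec.append(col)
            else:
                seen[key] = col
        report.add("duplicate_id", None, removed_dup, mat.shape[1] + len(removed_dup))
        report.add("duplicate_values", None, dup_vec, mat.shape[1])
        mat = mat.drop(columns=dup_vec)
    return mat, report


def filter_subjects(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    min_visits: int = 4,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove all samples of subjects who attended fewer than ``min_visits``."""
    report = QCReport()
    if matrix.shape[0] == 0:
        report.add("min_visits", min_visits, [], 0)
        return matrix, report
    cohort = cohort.loc[matrix.index]
    counts = cohort.groupby("subject")["visit"].nunique()
    removed_subjects = list(counts.index[counts < min_visits])
    keep_rows = ~cohort["subject"].isin(removed_subjects).to_numpy()
    report.add("min_visits", min_visits, removed_subjects, counts.size)
    return matrix.loc[keep_rows], report


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, the number of heterozygotes
    under HWE follows

        P(n_ab | n, n_a) = C * 2^n_ab * n! / (n_aa! n_ab! n_bb!)

    normalised over all heterozygote counts with the right parity.  The
    p-value sums the probabilities of all configurations no more likely than
    the observed one (two-sided by probability ordering), as in the standard
    exact test used by PLINK.
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    na = 2 * n_aa + n_ab  # minor-allele count (either allele works by symmetry)
    rare = min(na, 2 * n - na)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_ab]
    if p_obs.size == 0:
        raise ValueError("inconsistent genotype counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def qc_genotypes(
    genotypes: GenotypeData,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    max_missing: float = 0.05,
) -> tuple[GenotypeData, QCReport]:
    """Variant and subject QC: missingness, then MAF, then exact HWE.

    Variants with missing fraction > ``max_missing``, empirical MAF <
    ``maf_min`` (monomorphic variants fall under this rule), or exact-HWE
    P < ``hwe_alpha`` are removed; subjects with genotyping rate below
    ``1 - max_missing`` are removed first.
    """
    report = QCReport()
    dos = genotypes.dosage
    vals = dos.to_numpy(float)
    ok = np.isin(vals, (0.0, 1.0, 2.0)) | np.isnan(vals)
    if not ok.all():
        raise ValueError("dosages must be 0/1/2 or missing")

    subj_rate = 1.0 - dos.isna().mean(axis=1)
    removed_subj = list(dos.index[subj_rate < 1.0 - max_missing])
    report.add("subject_call_rate", 1.0 - max_missing, removed_subj, dos.shape[0])
    dos = dos.drop(index=removed_subj)

    var_miss = dos.isna().mean(axis=0)
    removed_miss = list(dos.columns[var_miss > max_missing])
    report.add("variant_missingness", max_missing, removed_miss, dos.shape[1])
    dos = dos.drop(columns=removed_miss)

    freq = dos.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    removed_maf = list(dos.columns[(maf < maf_min) | maf.isna()])
    report.add("maf", maf_min, removed_maf, dos.shape[1])
    dos = dos.drop(columns=removed_maf)

    removed_hwe = []
    for col in dos.columns:
        g = dos[col].dropna().to_numpy()
        counts = ((g == 0).sum(), (g == 1).sum(), (g == 2).sum())
        if hwe_exact_pvalue(*counts) < hwe_alpha:
            removed_hwe.append(col)
    report.add("hwe_exact", hwe_alpha, removed_hwe, dos.shape[1])
    dos = dos.drop(columns=removed_hwe)

    info = genotypes.info.loc[dos.columns]
    return GenotypeData(dos, info), report
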