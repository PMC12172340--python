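"""Synthetic longitudinal multi-omics cohort with planted ground truth.

The generator emulates a wellness-profiling design: ~100 subjects followed
over 24 months, visits every 3 months in year one and every 6 months in year
two, log2-scale analyte abundances with per-subject random intercepts,
harmonic (cosinor) seasonal effects, additive genetic effects under
Hardy-Weinberg equilibrium, sex/age/BMI covariate effects, and
missing-completely-at-random cells.  Proteins carry cis-pQTLs and may affect
metabolites causally through a shared latent confounder, so that naive
regression of metabolite on protein is biased while the instrumental-variable
estimand equals the planted causal slope.  Five correlated metabolic-risk
indicators (BMI, HDL, SBP, glucose, triglycerides) are driven by a latent
two-component risk factor, HDL loading negatively.

Everything planted is recorded in a :class:`GroundTruth` so that each
downstream estimator can be benchmarked on parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "GroundTruth",
    "MetabolomeConfig",
    "ProteomeConfig",
    "RiskConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_metabolome",
    "simulate_proteome",
    "simulate_clinical",
    "simulate_study",
    "sample_index",
]

# Visit offsets in months from each subject's start month: quarterly in year
# one, then two visits at ~6-month intervals in year two.
_YEAR1_OFFSETS = (0, 3, 6, 9)
_YEAR2_STEP = 6


def sample_index(subjects: Sequence[str], visits: Sequence[int]) -> pd.Index:
    """Canonical sample id ``<subject>_v<visit>`` for (subject, visit) pairs."""
    return pd.Index([f"{s}_v{v}" for s, v in zip(subjects, visits)], name="sample_id")


@dataclass
class GenotypeData:
    """Dosage matrix (subjects x variants, values 0/1/2 or NaN) plus variant info.

    ``info`` is indexed by variant_id with columns chrom, pos, maf (the
    generating allele frequency for simulated data, the empirical frequency
    for data read from files).
    """

    dosage: pd.DataFrame
    info: pd.DataFrame

    @property
    def subjects(self) -> pd.Index:
        return self.dosage.index

    @property
    def variants(self) -> pd.Index:
        return self.dosage.columns

    def empirical_maf(self) -> pd.Series:
        freq = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study.

    seasonal          : analyte -> (amplitude, phase in [0, 2pi))
    mqtl_effects      : list of (variant_id, metabolite, beta)
    pqtl_effects      : list of (variant_id, protein, beta)
    causal_pm         : (protein, metabolite) -> causal slope theta
    confounder_loadings : analyte -> loading on the latent confounder U
    covariate_effects : analyte -> {"sex": g, "bmi": d, "age": e}
    variance_shares   : analyte -> component -> fraction of total variance
    risk_labels       : subject -> "high" | "low"
    """

    seasonal: dict = field(default_factory=dict)
    mqtl_effects: list = field(default_factory=list)
    pqtl_effects: list = field(default_factory=list)
    causal_pm: dict = field(default_factory=dict)
    confounder_loadings: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    variance_shares: dict = field(default_factory=dict)
    risk_labels: dict = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for name in asdict(self):
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, list):
                setattr(out, name, list(a) + list(b))
            else:
                merged = dict(a)
                merged.update(b)
                setattr(out, name, merged)
        return out


def _check_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


def simulate_genotypes(
    n_subjects: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeData:
    """Draw biallelic dosages under Hardy-Weinberg equilibrium.

    Per variant a minor-allele frequency is drawn uniformly from ``maf_range``
    and dosages are binomial(2, maf) across subjects, which is exactly the
    HWE genotype distribution.  Variants are spread over chromosomes 1-22
    with strictly increasing positions within a chromosome.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")

    rng = _check_seed(seed)
    maf = rng.uniform(lo, hi, size=n_variants)
    dosage = rng.binomial(2, maf[None, :], size=(n_subjects, n_variants)).astype(float)

    subjects = pd.Index([f"S{i + 1:04d}" for i in range(n_subjects)], name="subject")
    variant_ids = pd.Index([f"var{i + 1:05d}" for i in range(n_variants)], name="variant_id")
    chrom = (np.arange(n_variants) % 22) + 1
    pos = np.zeros(n_variants, dtype=int)
    for c in range(1, 23):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.sort(rng.integers(1, 250_000_000, size=idx.size))
    info = pd.DataFrame({"chrom": chrom, "pos": pos, "maf": maf}, index=variant_ids)
    return GenotypeData(pd.DataFrame(dosage, index=subjects, columns=variant_ids), info)


def simulate_cohort(
    n_subjects: int = 100,
    n_visits: int = 6,
    start_months: Sequence[int] | None = None,
    covariate_config: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the longitudinal design table.

    One row per (subject, visit) with sampling calendar month (1-12), sex
    (0 = male, 1 = female, ~1:1), age (uniform within ``age_range``), BMI with
    a small within-subject random-walk drift, and two lifestyle factors
    (smoking, binary per subject; exercise hours/week, per visit).

    Visits follow the study calendar: 3-month spacing for the first four
    visits (year one), 6-month spacing afterwards (year two).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    cfg = dict(age_range=(50.0, 65.0), bmi_mean=25.0, bmi_sd=3.0, bmi_drift_sd=0.3)
    if covariate_config:
        cfg.update(covariate_config)

    rng = _check_seed(seed)
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    sex = np.zeros(n_subjects, dtype=int)
    sex[rng.permutation(n_subjects)[: n_subjects // 2]] = 1
    age = rng.uniform(*cfg["age_range"], size=n_subjects)
    bmi0 = np.clip(rng.normal(cfg["bmi_mean"], cfg["bmi_sd"], size=n_subjects), 16.0, None)
    if start_months is None:
        start = rng.integers(1, 13, size=n_subjects)
    else:
        start = rng.choice(np.asarray(start_months, dtype=int), size=n_subjects)
    smoker = rng.binomial(1, 0.15, size=n_subjects)

    offsets = [
        _YEAR1_OFFSETS[v] if v < len(_YEAR1_OFFSETS)
        else _YEAR1_OFFSETS[-1] + _YEAR2_STEP * (v - len(_YEAR1_OFFSETS) + 1)
        for v in range(n_visits)
    ]
    rows = []
    for i, subj in enumerate(subjects):
        bmi = bmi0[i]
        for v in range(n_visits):
            month = (start[i] - 1 + offsets[v]) % 12 + 1
            rows.append(
                {
                    "subject": subj,
                    "visit": v + 1,
                    "month": month,
                    "sex": sex[i],
                    "age": age[i],
                    "bmi": bmi,
                    "lifestyle_smoker": smoker[i],
                    "lifestyle_exercise": max(0.0, rng.normal(3.0, 2.0)),
                }
            )
            bmi = max(16.0, bmi + rng.normal(0.0, cfg["bmi_drift_sd"]))
    cohort = pd.DataFrame(rows)
    cohort.index = sample_index(cohort["subject"], cohort["visit"])
    return cohort


@dataclass
class MetabolomeConfig:
    """Effect sizes and noise for the metabolite generator (log2 scale).

    Defaults mirror the study conditions used throughout the benchmarks:
    between-subject sd 0.5 and residual sd 0.5 (inter-individual variation
    dominating intra-individual), a fifth of metabolites seasonal with
    amplitudes up to 0.5 log2 units, and sparse planted mQTLs of one log2
    unit per allele at common variants.
    """

    n_metabolites: int = 200
    mu_range: tuple[float, float] = (15.0, 25.0)
    sigma_subject: float = 0.5
    sigma_noise: float = 0.5
    seasonal_fraction: float = 0.2
    amplitude_range: tuple[float, float] = (0.1, 0.5)
    covariate_fraction: float = 0.3
    sex_effect_sd: float = 0.25
    bmi_effect_sd: float = 0.03
    age_effect_sd: float = 0.01
    n_mqtl: int = 3
    mqtl_beta: float = 1.0
    mqtl_min_maf: float = 0.2
    mqtl_effects: list | None = None  # explicit [(variant, metabolite, beta)]
    missing_rate: float = 0.05


def _planted_variance(
    amp: float,
    betas_g: list[tuple[str, float]],
    geno: GenotypeData,
    cov_eff: dict,
    cohort: pd.DataFrame,
    sigma_b: float,
    sigma_e: float,
) -> dict:
    comp = {
        "subject": sigma_b**2,
        "seasonal": amp**2 / 2.0,
        "residual": sigma_e**2,
    }
    gvar = 0.0
    for var, beta in betas_g:
        p = float(geno.info.loc[var, "maf"])
        gvar += beta**2 * 2.0 * p * (1.0 - p)
    comp["genetic"] = gvar
    comp["sex"] = cov_eff.get("sex", 0.0) ** 2 * 0.25
    comp["bmi"] = cov_eff.get("bmi", 0.0) ** 2 * float(np.var(cohort["bmi"]))
    comp["age"] = cov_eff.get("age", 0.0) ** 2 * float(np.var(cohort["age"]))
    total = sum(comp.values())
    return {k: v / total for k, v in comp.items()} if total > 0 else comp


def simulate_metabolome(
    cohort: pd.DataFrame,
    genotypes: GenotypeData,
    config: MetabolomeConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate log2 metabolite abundances over the cohort design.

    Per metabolite j and sample (i, v) with sampling month m:

        y = mu_j + b_i + A_j sin(2 pi m / 12 + phi_j) + sum_k beta_jk G_ik
            + gamma_j sex_i + delta_j (BMI_iv - mean BMI) + eta_j (age_i - mean age)
            + eps,   b_i ~ N(0, sigma_b^2),  eps ~ N(0, sigma_e^2)

    Covariates are centred so that mu_j stays the analyte's grand mean.
    Cells are then masked completely at random at ``missing_rate``.
    """
    cfg = config or MetabolomeConfig()
    missing = set(cohort["subject"].unique()) - set(genotypes.subjects)
    if missing:
        raise ValueError(f"cohort subjects absent from genotypes: {sorted(missing)[:5]}")
    rng = _check_seed(seed)

    n = len(cohort)
    M = cfg.n_metabolites
    names = [f"met{j + 1:04d}" for j in range(M)]
    subj_codes, subj_uniq = pd.factorize(cohort["subject"])
    month = cohort["month"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float) - 0.5
    bmi_c = cohort["bmi"].to_numpy(float) - cohort["bmi"].mean()
    age_c = cohort["age"].to_numpy(float) - cohort["age"].mean()

    mu = rng.uniform(*cfg.mu_range, size=M)
    truth = GroundTruth()

    # seasonal assignment
    n_seasonal = int(round(cfg.seasonal_fraction * M))
    seasonal_idx = rng.choice(M, size=n_seasonal, replace=False)
    amps = np.zeros(M)
    phases = np.zeros(M)
    amps[seasonal_idx] = rng.uniform(*cfg.amplitude_range, size=n_seasonal)
    phases[seasonal_idx] = rng.uniform(0.0, 2.0 * np.pi, size=n_seasonal)

    # covariate effects on a random subset
    gam = np.zeros(M)
    dlt = np.zeros(M)
    eta = np.zeros(M)
    cov_idx = rng.choice(M, size=int(round(cfg.covariate_fraction * M)), replace=False)
    gam[cov_idx] = rng.normal(0.0, cfg.sex_effect_sd, size=cov_idx.size)
    dlt[cov_idx] = rng.normal(0.0, cfg.bmi_effect_sd, size=cov_idx.size)
    eta[cov_idx] = rng.normal(0.0, cfg.age_effect_sd, size=cov_idx.size)

    # planted mQTLs
    if cfg.mqtl_effects is not None:
        mqtls = []
        for var, met, beta in cfg.mqtl_effects:
            if var not in genotypes.variants:
                raise ValueError(f"mQTL effect references unknown variant {var!r}")
            if met not in names:
                raise ValueError(f"mQTL effect references unknown metabolite {met!r}")
            mqtls.append((var, met, float(beta)))
    else:
        common = genotypes.info.index[genotypes.info["maf"] >= cfg.mqtl_min_maf]
        k = min(cfg.n_mqtl, len(common), M)
        vsel = rng.choice(len(common), size=k, replace=False)
        msel = rng.choice(M, size=k, replace=False)
        mqtls = [(common[vi], names[mi], cfg.mqtl_beta) for vi, mi in zip(vsel, msel)]

    b = rng.normal(0.0, cfg.sigma_subject, size=(len(subj_uniq), M))
    eps = rng.normal(0.0, cfg.sigma_noise, size=(n, M))
    Y = (
        mu[None, :]
        + b[subj_codes, :]
        + amps[None, :] * np.sin(2.0 * np.pi * month[:, None] / 12.0 + phases[None, :])
        + np.outer(sex, gam)
        + np.outer(bmi_c, dlt)
        + np.outer(age_c, eta)
        + eps
    )
    dos = genotypes.dosage.reindex(cohort["subject"]).to_numpy(float)
    by_met: dict[str, list[tuple[str, float]]] = {}
    for var, met, beta in mqtls:
        j = names.index(met)
        g = dos[:, genotypes.variants.get_loc(var)]
        Y[:, j] += beta * g
        by_met.setdefault(met, []).append((var, beta))

    if not (0.0 <= cfg.missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if cfg.missing_rate > 0:
        mask = rng.random(size=Y.shape) < cfg.missing_rate
        Y[mask] = np.nan

    matrix = pd.DataFrame(Y, index=cohort.index, columns=names)

    truth.mqtl_effects = mqtls
    for j, name in enumerate(names):
        truth.seasonal[name] = (float(amps[j]), float(phases[j]))
        truth.covariate_effects[name] = {
            "sex": float(gam[j]),
            "bmi": float(dlt[j]),
            "age": float(eta[j]),
        }
        truth.variance_shares[name] = _planted_variance(
            amps[j],
            by_met.get(name, []),
            genotypes,
            truth.covariate_effects[name],
            cohort,
            cfg.sigma_subject,
            cfg.sigma_noise,
        )
    return matrix, truth


@dataclass
class ProteomeConfig:
    """Protein (NPX-like, log2) generator with cis-pQTLs and causal effects.

    Each protein gets one cis-pQTL of effect ``pqtl_beta`` per allele.
    ``n_causal`` proteins causally shift a distinct metabolite with slope
    ``theta``; both load on a subject-level latent confounder U so that
    ordinary regression of metabolite on protein is biased upward while the
    IV estimand equals theta.
    """

    n_proteins: int = 100
    mu_range: tuple[float, float] = (2.0, 8.0)
    sigma_subject: float = 0.5
    sigma_noise: float = 0.5
    pqtl_beta: float = 1.0
    pqtl_min_maf: float = 0.2
    n_causal: int = 5
    theta: float = 0.5
    lambda_x: float = 0.5
    lambda_y: float = 0.5
    confounder_sd: float = 1.0
    causal_pm: dict | None = None  # explicit {(protein, metabolite): theta}
    missing_rate: float = 0.0


def simulate_proteome(
    cohort: pd.DataFrame,
    genotypes: GenotypeData,
    metabolome: pd.DataFrame,
    metabolome_truth: GroundTruth,
    config: ProteomeConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate proteins and inject causal protein->metabolite effects.

    Protein X for subject i, sample s:

        X_s = alpha + pi G_i + lambda_x U_i + b_i + e_s

    and for each causal pair the metabolite column is updated in place of a
    copy:  Y_s += theta X_s + lambda_y U_i.  Returns (proteins, updated
    metabolome, ground truth of the planted pQTL/causal/confounder structure).
    """
    cfg = config or ProteomeConfig()
    missing = set(cohort["subject"].unique()) - set(genotypes.subjects)
    if missing:
        raise ValueError(f"cohort subjects absent from genotypes: {sorted(missing)[:5]}")
    rng = _check_seed(seed)

    n = len(cohort)
    P = cfg.n_proteins
    names = [f"prot{j + 1:04d}" for j in range(P)]
    subj_codes, subj_uniq = pd.factorize(cohort["subject"])

    mu = rng.uniform(*cfg.mu_range, size=P)
    common = genotypes.info.index[genotypes.info["maf"] >= cfg.pqtl_min_maf]
    if len(common) < P:
        raise ValueError(
            f"need {P} variants with maf >= {cfg.pqtl_min_maf} for cis-pQTLs, "
            f"have {len(common)}"
        )
    pqtl_vars = common[rng.choice(len(common), size=P, replace=False)]

    U = rng.normal(0.0, cfg.confounder_sd, size=len(subj_uniq))
    b = rng.normal(0.0, cfg.sigma_subject, size=(len(subj_uniq), P))
    e = rng.normal(0.0, cfg.sigma_noise, size=(n, P))
    dos = genotypes.dosage.reindex(cohort["subject"]).to_numpy(float)
    gcols = np.array([genotypes.variants.get_loc(v) for v in pqtl_vars])
    X = (
        mu[None, :]
        + cfg.pqtl_beta * dos[:, gcols]
        + cfg.lambda_x * U[subj_codes, None]
        + b[subj_codes, :]
        + e
    )
    proteins = pd.DataFrame(X, index=cohort.index, columns=names)

    if cfg.causal_pm is not None:
        causal = {}
        for (prot, met), theta in cfg.causal_pm.items():
            if prot not in names:
                raise ValueError(f"causal effect references unknown protein {prot!r}")
            if met not in metabolome.columns:
                raise ValueError(f"causal effect references unknown metabolite {met!r}")
            causal[(prot, met)] = float(theta)
    else:
        k = min(cfg.n_causal, P, metabolome.shape[1])
        psel = rng.choice(P, size=k, replace=False)
        msel = rng.choice(metabolome.shape[1], size=k, replace=False)
        causal = {
            (names[pi], metabolome.columns[mi]): cfg.theta
            for pi, mi in zip(psel, msel)
        }

    metab = metabolome.copy()
    truth = GroundTruth()
    truth.pqtl_effects = [(str(v), p, cfg.pqtl_beta) for v, p in zip(pqtl_vars, names)]
    truth.causal_pm = causal
    for prot in names:
        truth.confounder_loadings[prot] = cfg.lambda_x
    for (prot, met), theta in causal.items():
        x = proteins[prot].to_numpy(float)
        metab[met] = (
            metab[met].to_numpy(float)
            + theta * x
            + cfg.lambda_y * U[subj_codes]
        )
        truth.confounder_loadings[met] = cfg.lambda_y

    if cfg.missing_rate > 0:
        mask = rng.random(size=proteins.shape) < cfg.missing_rate
        proteins = proteins.mask(mask)
    return proteins, metab, metabolome_truth.merge(truth)


@dataclass
class RiskConfig:
    """Two-component latent metabolic risk driving the clinical indicators.

    ``separation`` is the latent mean shift of the high-risk component in
    units of the per-indicator noise sd; at the default 3 the groups overlap
    realistically, at 6 they are linearly separable on BMI alone.
    """

    separation: float = 3.0
    p_high: float = 0.35
    # indicator -> (baseline, scale, loading on latent risk, sex offset in scales)
    indicators: dict = field(
        default_factory=lambda: {
            "bmi": (25.0, 3.0, 1.0, 0.2),
            "hdl": (1.5, 0.3, -1.0, 0.5),
            "sbp": (120.0, 12.0, 1.0, -0.3),
            "gluc": (5.5, 0.6, 1.0, -0.1),
            "tg": (1.2, 0.4, 1.0, -0.2),
        }
    )
    auxiliary: dict = field(
        default_factory=lambda: {
            "alat": (0.4, 0.15, 0.6, -0.3),
            "ggt": (0.5, 0.25, 0.6, -0.4),
            "urate": (300.0, 60.0, 0.6, -0.5),
            "tnt": (6.0, 2.0, 0.4, -0.2),
            "wbc": (6.0, 1.5, 0.4, 0.0),
        }
    )


def simulate_clinical(
    cohort: pd.DataFrame,
    risk_config: RiskConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the clinical indicator table per (subject, visit).

    Each subject belongs to a latent high/low risk component; indicator
    values are ``base + scale * (sex_off * sex + loading * z_i + noise)``
    with z_i = separation for high-risk subjects and 0 otherwise, clipped to
    stay positive.  Auxiliary liver/inflammation markers are elevated in the
    high-risk component the same way.
    """
    cfg = risk_config or RiskConfig()
    if cfg.separation < 0:
        raise ValueError("separation must be >= 0")
    hdl_loading = cfg.indicators["hdl"][2]
    if hdl_loading >= 0:
        raise ValueError("HDL must load negatively on the latent risk factor")
    rng = _check_seed(seed)

    subjects = cohort["subject"].unique()
    high = rng.random(len(subjects)) < cfg.p_high
    z = np.where(high, cfg.separation, 0.0)
    zmap = dict(zip(subjects, z))

    n = len(cohort)
    sex = cohort["sex"].to_numpy(float)
    zs = cohort["subject"].map(zmap).to_numpy(float)
    cols = {}
    for name, (base, scale, loading, sex_off) in {**cfg.indicators, **cfg.auxiliary}.items():
        noise = rng.normal(0.0, 1.0, size=n)
        vals = base + scale * (sex_off * sex + loading * zs + noise)
        cols[name] = np.clip(vals, 1e-3, None)
    clinical = pd.DataFrame(cols, index=cohort.index)
    truth = GroundTruth(
        risk_labels={s: ("high" if h else "low") for s, h in zip(subjects, high)}
    )
    return clinical, truth


@dataclass
class SimulatedStudy:
    cohort: pd.DataFrame
    genotypes: GenotypeData
    metabolome: pd.DataFrame
    proteome: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth
    class_terms: dict


def _synthetic_terms(analytes: Sequence[str], n_terms: int, rng: np.random.Generator) -> dict:
    """Random annotation-term universe (stand-in for curated class terms)."""
    terms = {}
    labels = [f"term{t + 1:02d}" for t in range(n_terms)]
    for a in analytes:
        k = 1 + rng.binomial(2, 0.3)
        terms[a] = set(rng.choice(labels, size=k, replace=False))
    return terms


def simulate_study(
    n_subjects: int = 100,
    n_visits: int = 6,
    n_variants: int = 500,
    metabolome_config: MetabolomeConfig | None = None,
    proteome_config: ProteomeConfig | None = None,
    risk_config: RiskConfig | None = None,
    n_terms: int = 20,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate a complete study: cohort, genotypes, omics, clinical, truth."""
    rng = _check_seed(seed)
    s = rng.integers(0, 2**31 - 1, size=6)
    cohort = simulate_cohort(n_subjects, n_visits, seed=int(s[0]))
    geno = simulate_genotypes(n_subjects, n_variants, seed=int(s[1]))
    metab, mtruth = simulate_metabolome(cohort, geno, metabolome_config, seed=int(s[2]))
    prot, metab, truth = simulate_proteome(
        cohort, geno, metab, mtruth, proteome_config, seed=int(s[3])
    )
    clinical, ctruth = simulate_clinical(cohort, risk_config, seed=int(s[4]))
    truth = truth.merge(ctruth)
    terms = _synthetic_terms(
        list(metab.columns), n_terms, np.random.default_rng(int(s[5]))
    )
    return SimulatedStudy(cohort, geno, metab, prot, clinical, truth, terms)
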