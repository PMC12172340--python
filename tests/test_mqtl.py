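"""Adjusted levels, GWAS scan vs OLS oracle, M_eff, pruning, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from longimet.mqtl import (
    adjusted_levels,
    bonferroni_threshold,
    conditional_refine,
    effective_tests,
    gwas_scan,
    ld_prune,
    meta_fixed,
)
from longimet.simulate import (
    GenotypeData,
    MetabolomeConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_metabolome,
)


def make_geno(dosages: dict, chrom=None, pos=None) -> GenotypeData:
    df = pd.DataFrame({k: np.asarray(v, float) for k, v in dosages.items()})
    df.index = pd.Index([f"S{i:03d}" for i in range(len(df))], name="subject")
    m = df.shape[1]
    info = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": pos if pos is not None else list(range(1, m + 1)),
            "maf": [0.3] * m,
        },
        index=df.columns,
    )
    return GenotypeData(df, info)


class TestAdjustedLevels:
    def test_balanced_no_visit_effect_equals_subject_mean(self):
        coh = simulate_cohort(6, 4, seed=1)
        rng = np.random.default_rng(2)
        mat = pd.DataFrame({"m": rng.normal(10, 1, len(coh))}, index=coh.index)
        lv = adjusted_levels(mat, coh)
        means = mat["m"].groupby(coh["subject"].to_numpy()).mean()
        # visit corrections shift all subjects identically in balanced data;
        # differences between subjects must match exactly
        diff = lv["m"] - means
        assert np.allclose(diff - diff.mean(), 0.0, atol=1e-10)

    def test_visit_effect_removed(self):
        coh = simulate_cohort(2, 2, seed=3)
        base = pd.DataFrame({"m": [1.0, 1.0, 3.0, 3.0]}, index=coh.index)
        shifted = base.copy()
        shifted.loc[coh["visit"].to_numpy() == 2, "m"] += 1.0
        lv0 = adjusted_levels(base, coh)["m"]
        lv1 = adjusted_levels(shifted, coh)["m"]
        np.testing.assert_allclose(lv0.to_numpy(), lv1.to_numpy(), atol=1e-10)

    def test_single_subject(self):
        coh = simulate_cohort(1, 3, seed=4)
        mat = pd.DataFrame({"m": [5.0, 6.0, 7.0]}, index=coh.index)
        lv = adjusted_levels(mat, coh)
        assert lv.shape == (1, 1)
        assert np.isfinite(lv.iloc[0, 0])

    def test_all_missing_subject_gets_nan(self):
        coh = simulate_cohort(3, 3, seed=5)
        vals = np.arange(9, dtype=float)
        vals[coh["subject"].to_numpy() == "S0002"] = np.nan
        lv = adjusted_levels(pd.DataFrame({"m": vals}, index=coh.index), coh)
        assert np.isnan(lv.loc["S0002", "m"])


class TestGWAS:
    def _inputs(self, n=60, n_var=8, seed=6):
        rng = np.random.default_rng(seed)
        geno = simulate_genotypes(n, n_var, maf_range=(0.2, 0.5), seed=seed)
        subjects = geno.subjects
        cov = pd.DataFrame(
            {
                "sex": rng.binomial(1, 0.5, n),
                "age": rng.uniform(50, 65, n),
                "bmi": rng.normal(25, 3, n),
            },
            index=subjects,
        )
        levels = pd.DataFrame(
            {"m1": rng.normal(size=n), "m2": rng.normal(size=n)}, index=subjects
        )
        return levels, geno, cov

    def test_matches_statsmodels_ols(self):
        levels, geno, cov = self._inputs()
        out = gwas_scan(levels, geno, cov).set_index(["variant_id", "metabolite"])
        for var in list(geno.variants[:4]):
            X = sm.add_constant(
                np.column_stack([geno.dosage[var], cov[["sex", "age", "bmi"]]])
            )
            fit = sm.OLS(levels["m1"], X).fit()
            row = out.loc[(var, "m1")]
            assert row["beta"] == pytest.approx(fit.params.iloc[1], abs=1e-10)
            assert row["se"] == pytest.approx(fit.bse.iloc[1], abs=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues.iloc[1], abs=1e-10)

    def test_null_pvalues_calibrated(self):
        rng = np.random.default_rng(7)
        n = 200
        geno = simulate_genotypes(n, 1000, maf_range=(0.1, 0.5), seed=8)
        cov = pd.DataFrame(
            {"sex": rng.binomial(1, 0.5, n), "age": rng.uniform(50, 65, n),
             "bmi": rng.normal(25, 3, n)},
            index=geno.subjects,
        )
        levels = pd.DataFrame({"m": rng.normal(size=n)}, index=geno.subjects)
        out = gwas_scan(levels, geno, cov)
        frac = (out["p"] < 0.05).mean()
        assert 0.036 <= frac <= 0.064  # 3 binomial SEs around 0.05 for 1000 tests

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(9)
        n = 96
        geno = simulate_genotypes(n, 5, maf_range=(0.3, 0.3), seed=10)
        cov = pd.DataFrame(
            {"sex": rng.binomial(1, 0.5, n), "age": rng.uniform(50, 65, n),
             "bmi": rng.normal(25, 3, n)},
            index=geno.subjects,
        )
        g = geno.dosage.iloc[:, 0].to_numpy()
        levels = pd.DataFrame({"m": 0.8 * g + rng.normal(0, 0.5, n)}, index=geno.subjects)
        out = gwas_scan(levels, geno, cov).set_index("variant_id")
        row = out.loc[geno.variants[0]]
        assert abs(row["beta"] - 0.8) < 3 * row["se"]

    def test_constant_dosage_skipped(self):
        levels, geno, cov = self._inputs(n=30, n_var=2)
        geno.dosage.iloc[:, 0] = 1.0
        out = gwas_scan(levels, geno, cov)
        assert geno.variants[0] not in set(out["variant_id"])
        assert geno.variants[1] in set(out["variant_id"])


class TestEffectiveTests:
    def test_independent_analytes(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.normal(size=(2000, 10)))
        assert effective_tests(mat) == 10

    def test_perfectly_correlated_pair(self):
        x = np.random.default_rng(12).normal(size=100)
        mat = pd.DataFrame({"a": x, "b": 2 * x + 1})
        assert effective_tests(mat) == 1

    def test_two_perfect_blocks(self):
        x = np.random.default_rng(13).normal(size=200)
        y = np.random.default_rng(14).normal(size=200)
        x = x - x.mean()
        y = y - y.mean()
        y = y - x * (x @ y) / (x @ x)  # exactly uncorrelated blocks
        mat = pd.DataFrame({f"a{i}": x * (i + 1) for i in range(5)}
                           | {f"b{i}": y * (i + 1) for i in range(5)})
        # block eigenvalues (5, 0, 0, 0, 0) each
        assert effective_tests(mat) == 2


class TestBonferroni:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(5e-8, 23) == pytest.approx(2.17e-9, rel=5e-3)
        assert bonferroni_threshold(5e-8, 6) == pytest.approx(8.33e-9, rel=5e-3)
        assert bonferroni_threshold(5e-8, 1) == 5e-8

    def test_invalid_m_eff(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(5e-8, 0)


class TestLDPrune:
    def _stats(self, variants, ps, geno):
        return pd.DataFrame(
            {
                "variant_id": variants,
                "chrom": [int(geno.info.loc[v, "chrom"]) for v in variants],
                "pos": [int(geno.info.loc[v, "pos"]) for v in variants],
                "metabolite": "m",
                "beta": 1.0,
                "se": 0.1,
                "p": ps,
                "n": geno.dosage.shape[0],
            }
        )

    def test_correlated_near_pair_keeps_smaller_p(self):
        g = np.random.default_rng(15).binomial(2, 0.3, 100)
        geno = make_geno({"v1": g, "v2": g}, pos=[1, 500_000])
        stats = self._stats(["v1", "v2"], [1e-10, 1e-8], geno)
        out = ld_prune(stats, geno)
        assert list(out["variant_id"]) == ["v1"]
        assert out.iloc[0]["pruned_partners"] == ["v2"]

    def test_correlated_far_pair_both_kept(self):
        g = np.random.default_rng(16).binomial(2, 0.3, 100)
        geno = make_geno({"v1": g, "v2": g}, pos=[1, 2_000_001])
        stats = self._stats(["v1", "v2"], [1e-10, 1e-8], geno)
        out = ld_prune(stats, geno)
        assert sorted(out["variant_id"]) == ["v1", "v2"]

    def test_chain_greedy_trace(self):
        # A-B r2 ~ 0.5, B-C r2 ~ 0.5, A-C r2 ~ 0: greedy keeps A then C
        rng = np.random.default_rng(17)
        n = 4000
        a = rng.binomial(2, 0.5, n).astype(float)
        c = rng.binomial(2, 0.5, n).astype(float)
        mix = rng.random(n)
        b = np.where(mix < 0.5, a, c)  # correlates with both a and c
        geno = make_geno({"A": a, "B": b, "C": c}, pos=[1, 100, 200])
        r2ab = np.corrcoef(a, b)[0, 1] ** 2
        r2bc = np.corrcoef(b, c)[0, 1] ** 2
        r2ac = np.corrcoef(a, c)[0, 1] ** 2
        assert r2ab > 0.1 and r2bc > 0.1 and r2ac < 0.1
        stats = self._stats(["A", "B", "C"], [1e-12, 1e-10, 1e-8], geno)
        out = ld_prune(stats, geno)
        assert list(out["variant_id"]) == ["A", "C"]

    def test_order_invariant_given_distinct_p(self):
        rng = np.random.default_rng(18)
        g = [rng.binomial(2, 0.3, 50).astype(float) for _ in range(4)]
        geno = make_geno({f"v{i}": g[i] for i in range(4)}, pos=[1, 10, 20, 30])
        stats = self._stats([f"v{i}" for i in range(4)], [1e-9, 1e-8, 1e-7, 1e-6], geno)
        out1 = ld_prune(stats, geno)
        out2 = ld_prune(stats.iloc[::-1].reset_index(drop=True), geno)
        assert list(out1["variant_id"]) == list(out2["variant_id"])


class TestConditional:
    def _cov(self, subjects, seed=19):
        rng = np.random.default_rng(seed)
        n = len(subjects)
        return pd.DataFrame(
            {"sex": rng.binomial(1, 0.5, n), "age": rng.uniform(50, 65, n),
             "bmi": rng.normal(25, 3, n)},
            index=subjects,
        )

    def test_duplicate_of_lead_dropped(self):
        rng = np.random.default_rng(20)
        g = rng.binomial(2, 0.3, 200).astype(float)
        geno = make_geno({"lead": g, "dup": g}, pos=[1, 2_000_000])
        levels = pd.DataFrame({"m": g + rng.normal(0, 0.3, 200)}, index=geno.subjects)
        pruned = pd.DataFrame(
            {
                "variant_id": ["lead", "dup"],
                "chrom": [1, 1],
                "pos": [1, 2_000_000],
                "metabolite": "m",
                "beta": [1.0, 1.0],
                "se": [0.1, 0.1],
                "p": [1e-20, 1e-19],
                "n": 200,
            }
        )
        out = conditional_refine(pruned, geno, levels, self._cov(geno.subjects))
        assert list(out["variant_id"]) == ["lead"]

    def test_two_independent_signals_both_retained(self):
        rng = np.random.default_rng(21)
        n = 500
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.3, n).astype(float)
        geno = make_geno({"v1": g1, "v2": g2}, chrom=[1, 2], pos=[1, 1])
        levels = pd.DataFrame(
            {"m": 0.8 * g1 + 0.8 * g2 + rng.normal(0, 0.5, n)}, index=geno.subjects
        )
        pruned = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "chrom": [1, 2],
                "pos": [1, 1],
                "metabolite": "m",
                "beta": [0.8, 0.8],
                "se": [0.05, 0.05],
                "p": [1e-30, 1e-28],
                "n": n,
            }
        )
        out = conditional_refine(pruned, geno, levels, self._cov(geno.subjects))
        assert sorted(out["variant_id"]) == ["v1", "v2"]
        non_lead = out[~out["is_lead"]]
        assert (non_lead["conditional_p"] < 0.01).all()

    def test_single_lead_passes_unconditionally(self):
        rng = np.random.default_rng(22)
        g = rng.binomial(2, 0.3, 100).astype(float)
        geno = make_geno({"v1": g})
        levels = pd.DataFrame({"m": g}, index=geno.subjects)
        pruned = pd.DataFrame(
            {"variant_id": ["v1"], "chrom": [1], "pos": [1], "metabolite": "m",
             "beta": [1.0], "se": [0.1], "p": [1e-10], "n": 100}
        )
        out = conditional_refine(pruned, geno, levels, self._cov(geno.subjects))
        assert len(out) == 1
        assert np.isnan(out.iloc[0]["conditional_p"])


class TestMeta:
    def test_single_cohort_identity(self):
        ms = meta_fixed([{"beta": 0.4, "se": 0.2}])
        assert ms.beta_meta == pytest.approx(0.4)
        assert ms.se_meta == pytest.approx(0.2)

    def test_equal_weights(self):
        ms = meta_fixed([{"beta": 0.7, "se": 0.3}, {"beta": 0.7, "se": 0.3}])
        assert ms.beta_meta == pytest.approx(0.7)
        assert ms.se_meta == pytest.approx(0.3 / np.sqrt(2))

    def test_hand_computed_weights(self):
        ms = meta_fixed([{"beta": 1.0, "se": 1.0}, {"beta": 0.0, "se": 1.0}])
        assert ms.beta_meta == pytest.approx(0.5)
        assert ms.se_meta == pytest.approx(1 / np.sqrt(2))

    def test_se_strictly_decreases_with_cohorts(self):
        cohorts = [{"beta": 0.1 * k, "se": 0.5 + 0.1 * k} for k in range(5)]
        ses = [meta_fixed(cohorts[: k + 1]).se_meta for k in range(5)]
        assert all(b < a for a, b in zip(ses, ses[1:]))

    def test_beta_in_convex_hull(self):
        ms = meta_fixed([{"beta": -0.2, "se": 0.5}, {"beta": 0.9, "se": 0.1}])
        assert -0.2 <= ms.beta_meta <= 0.9

    def test_allele_mismatch_rejected(self):
        with pytest.raises(ValueError, match="effect_allele"):
            meta_fixed(
                [{"beta": 1.0, "se": 1.0, "effect_allele": "A"},
                 {"beta": 1.0, "se": 1.0, "effect_allele": "G"}]
            )


class TestEndToEnd:
    def test_planted_mqtls_recovered_single_run(self):
        coh = simulate_cohort(96, 6, seed=23)
        geno = simulate_genotypes(96, 500, seed=24)
        cfg = MetabolomeConfig(n_metabolites=100, n_mqtl=3, mqtl_beta=1.0,
                               mqtl_min_maf=0.2, missing_rate=0.0)
        metab, truth = simulate_metabolome(coh, geno, cfg, seed=25)
        levels = adjusted_levels(metab, coh)
        cov = coh[coh["visit"] == 1].set_index("subject")[["sex", "age", "bmi"]]
        stats = gwas_scan(levels, geno, cov)
        thr = bonferroni_threshold(5e-8, effective_tests(metab))
        sig = stats[stats["p"] < thr]
        final = conditional_refine(ld_prune(sig, geno), geno, levels, cov)
        found = set(zip(final["variant_id"], final["metabolite"]))
        planted = {(v, m) for v, m, _ in truth.mqtl_effects}
        assert len(planted & found) >= 2
        assert len(found - planted) <= 1
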