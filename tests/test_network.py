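"""Protein-metabolite scan, instrument selection, 2SLS, network, tiers."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from longimet.benchmarks import brute_force_betweenness
from longimet.network import (
    build_network,
    lmm_scan,
    mr_2sls,
    select_instruments,
    tier_nodes,
)
from longimet.simulate import simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(100, 6, seed=30)


def protein_metabolite_pair(cohort, beta=0.8, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    n = len(cohort)
    subj = pd.factorize(cohort["subject"])[0]
    n_subj = subj.max() + 1
    prot = np.repeat(rng.normal(0, 0.5, n_subj), 1)[subj] + rng.normal(0, 0.5, n)
    met = beta * prot + rng.normal(0, 0.5, n_subj)[subj] + rng.normal(0, noise, n)
    return (
        pd.DataFrame({"met": met}, index=cohort.index),
        pd.DataFrame({"prot": prot}, index=cohort.index),
    )


class TestLMMScan:
    def test_planted_slope_recovered(self, cohort):
        met, prot = protein_metabolite_pair(cohort, beta=0.8, seed=1)
        out = lmm_scan(met, prot, cohort)
        assert len(out) == 1
        assert out.iloc[0]["beta"] == pytest.approx(0.8, abs=0.15)
        assert out.iloc[0]["q"] < 0.05

    def test_slope_recovery_over_replicates(self, cohort):
        # repeated-draw check of estimator accuracy at study size
        hits = 0
        for rep in range(30):
            met, prot = protein_metabolite_pair(cohort, beta=0.8, seed=100 + rep)
            out = lmm_scan(met, prot, cohort)
            if abs(out.iloc[0]["beta"] - 0.8) <= 0.1:
                hits += 1
        assert hits >= 27  # >= 90% within +-0.1

    def test_null_calibration(self, cohort):
        # independent protein/metabolite pairs: p uniform
        rng = np.random.default_rng(31)
        n = len(cohort)
        subj = pd.factorize(cohort["subject"])[0]
        n_pairs = 500
        mets = pd.DataFrame(
            rng.normal(0, 0.5, (100, n_pairs))[subj] + rng.normal(0, 0.5, (n, n_pairs)),
            index=cohort.index,
            columns=[f"m{j}" for j in range(n_pairs)],
        )
        prots = pd.DataFrame(
            rng.normal(0, 0.5, (100, 1))[subj] + rng.normal(0, 0.5, (n, 1)),
            index=cohort.index,
            columns=["p0"],
        )
        out = lmm_scan(mets, prots, cohort)
        frac = float((out["p"] < 0.05).mean())
        # 3 binomial SEs around 0.05 at 500 tests
        assert 0.021 <= frac <= 0.079

    def test_constant_protein_skipped(self, cohort):
        met, prot = protein_metabolite_pair(cohort, seed=3)
        prot["flat"] = 1.0
        out = lmm_scan(met, prot, cohort)
        assert set(out["protein"]) == {"prot"}


class TestInstruments:
    def _stats(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "protein", "beta", "se", "p"]
        )

    def test_pleiotropic_variant_removed_everywhere(self):
        rows = [["v1", 1, 100, f"p{i}", 1.0, 0.1, 1e-10] for i in range(6)]
        rows += [["v2", 1, 200, "p0", 1.0, 0.1, 1e-10]]
        ivs = select_instruments(self._stats(rows))
        assert all("v1" not in v for v in ivs.values())
        assert ivs["p0"] == ["v2"]

    def test_five_associations_is_boundary_retained(self):
        rows = [["v1", 1, 100, f"p{i}", 1.0, 0.1, 1e-10] for i in range(5)]
        ivs = select_instruments(self._stats(rows))
        assert all("v1" in v for v in ivs.values())

    def test_empty_stats_empty_map(self):
        assert select_instruments(self._stats([])) == {}

    def test_subthreshold_not_instrument(self):
        rows = [["v1", 1, 100, "p0", 1.0, 0.1, 1e-6]]
        assert select_instruments(self._stats(rows)) == {}


class TestTwoSLS:
    def test_wald_ratio_identity_single_instrument(self):
        rng = np.random.default_rng(40)
        n = 400
        idx = pd.Index([f"S{i}" for i in range(n)])
        sex = rng.binomial(1, 0.5, n).astype(float)
        covs = pd.DataFrame({"sex": sex, "age": rng.uniform(50, 65, n)}, index=idx)
        G = rng.binomial(2, 0.3, n).astype(float)
        X = G + 0.4 * sex + rng.normal(0, 1, n)
        Y = 0.5 * X - 0.3 * sex + rng.normal(0, 1, n)
        rec = mr_2sls(
            pd.Series(Y, idx), pd.Series(X, idx), pd.DataFrame({"g": G}, index=idx),
            covariates=covs,
        )
        W = np.column_stack([np.ones(n), covs.to_numpy()])
        res = lambda v: v - W @ np.linalg.lstsq(W, v, rcond=None)[0]
        wald = (res(G) @ res(Y)) / (res(G) @ res(X))
        assert rec.theta_hat == pytest.approx(wald, abs=1e-10)

    def test_null_theta_centred_at_zero(self):
        rng = np.random.default_rng(41)
        thetas = []
        idx = pd.Index([f"S{i}" for i in range(500)])
        for rep in range(50):
            G = rng.binomial(2, 0.3, 500).astype(float)
            X = G + rng.normal(0, 1, 500)
            Y = rng.normal(0, 1, 500)
            rec = mr_2sls(pd.Series(Y, idx), pd.Series(X, idx),
                          pd.DataFrame({"g": G}, index=idx))
            thetas.append(rec.theta_hat)
        assert abs(np.mean(thetas)) < 0.03

    def test_bias_dominance_under_confounding(self):
        # |mean(2SLS) - theta| < |mean(OLS) - theta| over replicates
        rng = np.random.default_rng(42)
        idx = pd.Index([f"S{i}" for i in range(500)])
        iv_est, ols_est = [], []
        for rep in range(100):
            G = rng.binomial(2, 0.3, 500).astype(float)
            U = rng.normal(0, 1, 500)
            X = G + U + rng.normal(0, 1, 500)
            Y = 0.5 * X + U + rng.normal(0, 1, 500)
            rec = mr_2sls(pd.Series(Y, idx), pd.Series(X, idx),
                          pd.DataFrame({"g": G}, index=idx))
            iv_est.append(rec.theta_hat)
            ols_est.append(np.cov(X, Y)[0, 1] / np.var(X))
        assert abs(np.mean(iv_est) - 0.5) < abs(np.mean(ols_est) - 0.5)
        assert abs(np.mean(iv_est) - 0.5) < 0.05

    def test_weak_instrument_flagged(self):
        rng = np.random.default_rng(43)
        n = 200
        idx = pd.Index([f"S{i}" for i in range(n)])
        G = rng.binomial(2, 0.3, n).astype(float)
        X = 0.01 * G + rng.normal(0, 1, n)
        Y = rng.normal(0, 1, n)
        rec = mr_2sls(pd.Series(Y, idx), pd.Series(X, idx),
                      pd.DataFrame({"g": G}, index=idx))
        assert rec.weak_instruments and rec.first_stage_F < 10

    def test_zero_variance_instrument_dropped_then_error(self):
        idx = pd.Index([f"S{i}" for i in range(50)])
        rng = np.random.default_rng(44)
        with pytest.raises(ValueError, match="instrument"):
            mr_2sls(
                pd.Series(rng.normal(size=50), idx),
                pd.Series(rng.normal(size=50), idx),
                pd.DataFrame({"g": np.ones(50)}, index=idx),
            )


class TestBuildNetwork:
    def _lmm(self, rows):
        df = pd.DataFrame(rows, columns=["protein", "metabolite", "beta", "p", "q"])
        df["sign"] = np.where(df["beta"] >= 0, "+", "-")
        return df

    def test_no_significant_pairs_empty_graph(self):
        lmm = self._lmm([["p1", "m1", 0.5, 0.5, 0.9]])
        mr = pd.DataFrame(columns=["protein", "metabolite", "theta_hat", "p"])
        g = build_network(lmm, mr)
        assert g.number_of_nodes() == 0

    def test_single_mr_supported_edge(self):
        lmm = self._lmm([["p1", "m1", 0.5, 1e-6, 1e-5]])
        mr = pd.DataFrame([{"protein": "p1", "metabolite": "m1",
                            "theta_hat": 0.4, "p": 1e-4}])
        g = build_network(lmm, mr)
        assert g.number_of_nodes() == 2
        assert g.edges["p1", "m1"]["kind"] == "lmm+mr"

    def test_mr_without_lmm_skipped_with_warning(self):
        lmm = self._lmm([["p1", "m1", 0.5, 1e-6, 1e-5]])
        mr = pd.DataFrame([{"protein": "p2", "metabolite": "m2",
                            "theta_hat": 0.4, "p": 1e-4}])
        with pytest.warns(UserWarning, match="not LMM-significant"):
            g = build_network(lmm, mr)
        assert "p2" not in g

    def test_bipartite(self):
        lmm = self._lmm(
            [["p1", "m1", 0.5, 1e-6, 1e-5], ["p1", "m2", 0.4, 1e-5, 1e-4],
             ["p2", "m1", -0.3, 1e-4, 1e-3]]
        )
        mr = pd.DataFrame(columns=["protein", "metabolite", "theta_hat", "p"])
        g = build_network(lmm, mr)
        kinds = nx.get_node_attributes(g, "kind")
        assert all(kinds[u] != kinds[v] for u, v in g.edges)


class TestTiers:
    def test_star_hub_tier1(self):
        ta = tier_nodes(nx.star_graph(8))
        t = ta.table.set_index("node")
        assert t.loc[0, "betweenness"] == 28.0  # C(8,2) leaf pairs
        assert t.loc[0, "tier"] == "1"
        assert (t.drop(0)["tier"] == "other").all()
        assert ta.median == 0.0 and ta.mad == 0.0

    def test_complete_graph_all_other(self):
        ta = tier_nodes(nx.complete_graph(5))
        assert (ta.table["tier"] == "other").all()

    def test_path_graph_scores_and_tiers(self):
        ta = tier_nodes(nx.path_graph(5))
        t = ta.table.set_index("node")
        np.testing.assert_allclose(
            t.loc[[0, 1, 2, 3, 4], "betweenness"], [0, 3, 4, 3, 0]
        )
        assert (t["tier"] == "other").all()  # median 3, MAD 1: max 4 <= 3+1? no, 4 > 4 false

    def test_two_node_graph_all_other(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        ta = tier_nodes(g)
        assert (ta.table["tier"] == "other").all()

    def test_matches_brute_force_oracle_random_graphs(self):
        rng = np.random.default_rng(45)
        for i in range(30):
            g = nx.gnp_random_graph(
                int(rng.integers(3, 13)), float(rng.uniform(0.2, 0.6)),
                seed=int(rng.integers(2**31 - 1)),
            )
            ta = tier_nodes(g)
            oracle = brute_force_betweenness(g)
            got = dict(zip(ta.table["node"], ta.table["betweenness"]))
            for v, s in oracle.items():
                assert got[v] == pytest.approx(s, abs=1e-9)
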