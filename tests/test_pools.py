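"""Functional pools, cluster labelling, and the logistic LRT."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ldprscan.pools import (
    ARMS_RACE_PATTERNS,
    FunctionPool,
    build_pool,
    fit_pool_lrt,
    homology_pool,
    label_pool_clusters,
)
from ldprscan.simulate import GO_CLOSURE, GO_INTERSPECIES_ROOT, simulate_cluster_evidence

CLOSURE = {t: set(a) for t, a in GO_CLOSURE.items()}


def _meta(rows):
    return pd.DataFrame(rows, columns=["gene_id", "descriptor", "go_terms", "pool_label"])


class TestBuildPool:
    def test_empty_selectors_rejected(self):
        with pytest.raises(ValueError):
            build_pool(_meta([]))

    def test_no_match_empty_pool(self):
        meta = _meta([("g1", "MADS-box protein", "GO:0008150", "neutral")])
        pool = build_pool(meta, go_root_id="GO:9999999", descriptor_patterns=[])
        assert pool.gene_ids == set()

    def test_descriptor_regex_selection(self):
        meta = _meta(
            [
                ("g1", "putative leucine-rich repeat protein", "-", "x"),
                ("g2", "Thionin precursor", "-", "x"),
                ("g3", "actin", "-", "x"),
                ("g4", "MADS-box protein", "-", "x"),
                ("g5", "cytochrome P450", "-", "x"),
            ]
        )
        pool = build_pool(
            meta, descriptor_patterns=["(?i)leucine-rich repeat", "(?i)thionin"]
        )
        assert pool.gene_ids == {"g1", "g2"}
        assert pool.provenance["g1"] == "descriptor_regex"

    def test_go_closure_selection(self):
        meta = _meta(
            [
                ("g1", "x", "GO:0009617", "x"),           # child of the root via closure
                ("g2", "x", "GO:0044419", "x"),           # the root itself
                ("g3", "x", "GO:0008150", "x"),           # unrelated
                ("g4", "x", "GO:0008150;GO:0050832", "x"),  # second term hits
            ]
        )
        pool = build_pool(meta, go_root_id=GO_INTERSPECIES_ROOT, go_closure=CLOSURE)
        assert pool.gene_ids == {"g1", "g2", "g4"}
        assert all(pool.provenance[g] == "go_term" for g in pool.gene_ids)

    def test_recovers_simulator_truth_labels(self, seed7):
        """On synthetic metadata the GO + descriptor pool equals the planted
        arms-race gene set exactly."""
        sim = seed7.sim
        pool = build_pool(
            sim.metadata,
            go_root_id=GO_INTERSPECIES_ROOT,
            descriptor_patterns=ARMS_RACE_PATTERNS,
            go_closure=CLOSURE,
        )
        truth_pool = {
            g for g, lab in sim.truth.pool_label_of_gene.items() if lab == "arms_race"
        }
        assert pool.gene_ids == truth_pool


class TestLabelPoolClusters:
    def test_exact_half_is_not_majority(self):
        pool = FunctionPool("p", {"g1"}, {})
        labels = label_pool_clusters({"cl": ["g1", "g2"]}, pool)
        assert labels == {"cl": False}

    def test_singleton_in_pool_labelled(self):
        pool = FunctionPool("p", {"g1"}, {})
        assert label_pool_clusters({"cl": ["g1"]}, pool) == {"cl": True}

    def test_against_ratio_oracle(self):
        rng = np.random.default_rng(0)
        clusters = {
            f"cl{i}": [f"g{i}_{j}" for j in range(int(rng.integers(1, 9)))]
            for i in range(50)
        }
        all_genes = [g for m in clusters.values() for g in m]
        pool_genes = {g for g in all_genes if rng.random() < 0.4}
        pool = FunctionPool("p", pool_genes, {})
        labels = label_pool_clusters(clusters, pool)
        for cid, members in clusters.items():
            frac = sum(g in pool_genes for g in members) / len(members)
            assert labels[cid] == (frac > 0.5)


class TestHomologyPool:
    TABLE = pd.DataFrame(
        {
            "query": ["g1.1", "g2.1", "g2.2", "g3.1"],
            "subject": ["hk1", "hk2", "hk2", "hk3"],
            "aligned_length": [1000, 450, 900, 810],
            "query_length": [1000, 900, 1000, 1000],
            "subject_length": [1000, 900, 1000, 1000],
        }
    )

    def test_full_coverage_selected(self):
        pool = homology_pool(self.TABLE)
        assert "g1" in pool.gene_ids

    def test_half_coverage_rejected_but_any_variant_counts(self):
        pool = homology_pool(self.TABLE)
        # g2.1 covers 50% (rejected) but g2.2 covers 90%
        assert "g2" in pool.gene_ids
        assert pool.provenance["g2"] == "homology"

    def test_hand_computed_filter(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(20):
            ql, sl = int(rng.integers(500, 1_500)), int(rng.integers(500, 1_500))
            al = int(rng.integers(0, min(ql, sl) + 1))
            rows.append((f"g{i}.1", "ref", al, ql, sl))
        table = pd.DataFrame(
            rows, columns=["query", "subject", "aligned_length", "query_length", "subject_length"]
        )
        pool = homology_pool(table, coverage=0.8)
        expected = {
            f"g{i}" for i, (_, _, al, ql, sl) in enumerate(rows) if al / ((ql + sl) / 2) > 0.8
        }
        assert pool.gene_ids == expected

    def test_max_denominator_variant(self):
        pool = homology_pool(self.TABLE, denominator="max")
        assert "g3" in pool.gene_ids  # 810/1000 > 0.8 under both definitions

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            homology_pool(pd.DataFrame({"query": []}))


class TestFitPoolLrt:
    def test_constant_predictor_no_information(self):
        y = np.array([0.0, 1, 0, 1, 1])
        p = np.full(5, 0.2)
        res = fit_pool_lrt(y, p)
        assert res.lrt_stat == 0.0 and res.p_value == 1.0 and res.beta1 == 0.0

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        y, p = simulate_cluster_evidence(n_clusters=300, beta0=-2.0, beta1=1.0, seed=4)
        res = fit_pool_lrt(y, p)
        x = -np.log(p)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert math.isclose(res.beta0, fit.params[0], abs_tol=1e-8)
        assert math.isclose(res.beta1, fit.params[1], abs_tol=1e-8)
        assert math.isclose(res.ll_full, fit.llf, abs_tol=1e-8)
        assert math.isclose(res.p_value, fit.llr_pvalue, rel_tol=1e-6)

    def test_nesting_inequality(self):
        for seed in range(10):
            y, p = simulate_cluster_evidence(n_clusters=80, beta0=-1.0, beta1=0.3, seed=seed)
            if y.sum() in (0, len(y)):
                continue
            res = fit_pool_lrt(y, p)
            assert res.ll_full >= res.ll_null - 1e-8
            assert res.lrt_stat >= 0.0

    def test_separation_warns_and_still_reports(self):
        x = np.array([0.1, 0.2, 0.3, 2.0, 2.5, 3.0])
        y = np.array([0.0, 0, 0, 1, 1, 1])
        with pytest.warns(RuntimeWarning, match="separation"):
            res = fit_pool_lrt(y, np.exp(-x))
        assert res.separation
        assert 0.0 < res.p_value < 1.0

    def test_nan_pvalues_excluded_or_imputed(self):
        labels = {"a": True, "b": False, "c": True, "d": False}
        pvals = {"a": 0.001, "b": 0.8, "c": float("nan"), "d": 0.5}
        res_excl = fit_pool_lrt(labels, pvals)
        assert res_excl.n_clusters == 3
        res_imp = fit_pool_lrt(labels, pvals, impute_ineligible=True)
        assert res_imp.n_clusters == 4

    def test_all_one_class(self):
        res = fit_pool_lrt(np.zeros(10), np.linspace(0.01, 0.9, 10))
        assert res.p_value == 1.0 and res.lrt_stat == 0.0

    def test_type_one_error_calibration(self):
        """With labels independent of the evidence the LRT rejects at ~alpha
        (rate inside the binomial 95% band around 0.05 over 400 label sets)."""
        n_reps, rej = 400, 0
        for seed in range(n_reps):
            y, p = simulate_cluster_evidence(n_clusters=300, beta0=-2.2, beta1=0.0, seed=seed)
            if y.sum() in (0, len(y)):
                continue
            rej += fit_pool_lrt(y, p).p_value < 0.05
        rate = rej / n_reps
        half = 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_power_and_recovery(self):
        """With beta1 = 1 and 300 clusters the LRT is essentially always
        significant and the slope estimate is nearly unbiased."""
        rej, betas = 0, []
        for seed in range(100):
            y, p = simulate_cluster_evidence(n_clusters=300, beta0=-2.5, beta1=1.0, seed=seed)
            res = fit_pool_lrt(y, p)
            rej += res.p_value < 0.05
            betas.append(res.beta1)
        assert rej >= 90
        assert abs(float(np.median(betas)) - 1.0) <= 0.1
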