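"""Expression association: preprocessing, both approaches, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affinityqtl import association as assoc
from affinityqtl.affinity import AffinityVariant
from affinityqtl.crm import CRM, GenomicInterval, Haplotype, HaplotypeSet


def make_variant(scores):
    return AffinityVariant(
        crm_id="c",
        tf="t",
        log_fca=tuple(scores),
        ref_best_a=0.01,
        ref_best_haplotype=0,
        invariant=False,
    )


def make_hapset(hap_of_chrom):
    """Haplotype set over len(hap_of_chrom) chromosome copies."""
    n_haps = max(hap_of_chrom) + 1
    haps = []
    for k in range(n_haps):
        carriers = tuple(i for i, h in enumerate(hap_of_chrom) if h == k)
        haps.append(Haplotype(sequence="A" * (k + 2), alleles=(k,), carriers=carriers))
    return HaplotypeSet(crm_id="c", haplotypes=tuple(haps), reference_index=0)


class TestExpressionPreprocessing:
    def test_filter_expressed_strict_majority_rule(self):
        n = 359
        rows = {
            "just_over": [0] * 180 + [5] * (n - 180),   # 50.1% zeros -> removed
            "just_under": [0] * 179 + [5] * (n - 179),  # 49.9% zeros -> retained
            "all_zero": [0] * n,
        }
        counts = pd.DataFrame(rows).T
        assert assoc.filter_expressed(counts) == ["just_under"]

    def test_rank_transform_closed_form(self):
        out = assoc.rank_transform([1.0, 2.0, 3.0])
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[1] == 0.0

    def test_rank_transform_monotone_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            assoc.rank_transform(x), assoc.rank_transform(np.exp(3 * x)), atol=1e-12
        )

    def test_rank_transform_constant_rejected(self):
        with pytest.raises(ValueError):
            assoc.rank_transform([1.0, 1.0, 1.0])


class TestClassification:
    def test_two_haplotype_strong_case(self):
        c = assoc.classify_haplotypes(make_variant([0.0, -1.0]))
        assert c.threshold == pytest.approx(-0.8)
        assert c.labels == ("high", "low")

    def test_two_haplotype_moderate_case(self):
        c = assoc.classify_haplotypes(make_variant([0.0, -0.5]))
        assert c.threshold == pytest.approx(-0.4)
        assert c.labels == ("high", "low")

    def test_unclassified_band(self):
        c = assoc.classify_haplotypes(make_variant([0.0, -0.25, -1.0]))
        assert c.labels == ("high", "unclassified", "low")

    def test_no_low_candidate_drops_variant(self):
        assert assoc.classify_haplotypes(make_variant([0.0, -0.2])) is None

    def test_dosage_counts_low_alleles(self):
        classes = assoc.classify_haplotypes(make_variant([0.0, -1.0]))
        hs = make_hapset([1, 1, 0, 1, 0, 0])
        dosage = assoc.encode_dosage(classes, hs)
        np.testing.assert_array_equal(dosage, [2.0, 1.0, 0.0])

    def test_unclassified_carrier_excluded(self):
        classes = assoc.classify_haplotypes(make_variant([0.0, -0.25, -1.0]))
        hs = make_hapset([0, 1, 2, 2, 0, 0])
        dosage = assoc.encode_dosage(classes, hs)
        assert np.isnan(dosage[0])          # carries the unclassified haplotype
        assert dosage[1] == 2.0             # two low copies
        assert dosage[2] == 0.0


class TestThresholdedModel:
    def test_noiseless_fit(self, rng):
        x = rng.binomial(2, 0.4, size=50).astype(float)
        X = pd.DataFrame({"v1": x})
        res = assoc.fit_gene_model_thresholded(x.copy(), X, gene="g")
        assert res.anova_p < 1e-10
        assert res.variant_stats["beta"].iloc[0] == pytest.approx(1.0)

    def test_duplicated_predictor_collapsed(self, rng):
        x = rng.binomial(2, 0.4, size=60).astype(float)
        X = pd.DataFrame({"v1": x, "v2": x.copy()})
        y = x + rng.normal(0, 0.1, size=60)
        res = assoc.fit_gene_model_thresholded(y, X, gene="g")
        assert list(res.variant_stats["variant"]) == ["v1"]
        assert res.groups == {"v1": ["v1", "v2"]}

    def test_anticorrelated_predictor_collapsed(self, rng):
        x = rng.binomial(2, 0.4, size=60).astype(float)
        X = pd.DataFrame({"v1": x, "v2": 2.0 - x})
        res = assoc.fit_gene_model_thresholded(
            x + rng.normal(0, 0.1, 60), X, gene="g"
        )
        assert list(res.variant_stats["variant"]) == ["v1"]

    def test_ols_matches_normal_equations(self, rng):
        n, k = 80, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=list("abc"))
        y = rng.normal(size=n)
        res = assoc.fit_gene_model_thresholded(y, X, gene="g")
        design = np.column_stack([np.ones(n), X.to_numpy()])
        beta_ref = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(
            res.variant_stats["beta"].to_numpy(), beta_ref[1:], atol=1e-8
        )

    def test_excluded_individuals_complete_case(self, rng):
        x = rng.binomial(2, 0.4, size=50).astype(float)
        x2 = x.copy()
        x2[:5] = np.nan
        res = assoc.fit_gene_model_thresholded(
            x, pd.DataFrame({"v1": x2}), gene="g"
        )
        assert res.n == 45

    def test_too_few_individuals_raise(self):
        X = pd.DataFrame({"v1": [0.0, 1.0]})
        with pytest.raises(ValueError):
            assoc.fit_gene_model_thresholded(np.array([0.5, 1.5]), X, gene="g")


class TestFdr:
    def _res(self, gene, p):
        return assoc.GeneAssociationResult(
            gene=gene,
            approach="thresholded",
            n=100,
            anova_p=p,
            variant_stats=pd.DataFrame(
                {"variant": [f"{gene}:v"], "beta": [1.0], "p": [0.01]}
            ),
        )

    def test_bh_hand_case(self):
        results = [self._res(g, p) for g, p in zip("abc", (0.001, 0.002, 0.9))]
        hits = assoc.fdr_and_coefficients(results)
        qs = {r.gene: r.fdr_q for r in results}
        assert qs["a"] == pytest.approx(0.003)
        assert qs["b"] == pytest.approx(0.003)
        assert qs["c"] == pytest.approx(0.9)
        assert set(hits["gene"]) == {"a", "b"}

    def test_all_null_no_genes_pass(self):
        results = [self._res(g, 1.0) for g in "abc"]
        assert len(assoc.fdr_and_coefficients(results)) == 0

    def test_single_gene_identity(self):
        results = [self._res("a", 0.05)]
        hits = assoc.fdr_and_coefficients(results)
        assert results[0].fdr_q == pytest.approx(0.05)
        assert len(hits) == 1

    def test_coefficient_gate(self):
        r = self._res("a", 0.001)
        r.variant_stats.loc[0, "p"] = 0.2  # gene passes, variant does not
        assert len(assoc.fdr_and_coefficients([r])) == 0


class TestThresholdFreePredictors:
    def test_homozygous_reference_zero(self):
        v = make_variant([0.0, -0.3])
        hs = make_hapset([0, 0, 1, 1])
        x = assoc.build_threshold_free_predictors(v, hs)
        assert x[0] == 0.0
        assert x[1] == pytest.approx(-0.6)

    def test_additivity(self):
        v = make_variant([-0.3, -0.1])
        hs = make_hapset([0, 1])
        assert assoc.build_threshold_free_predictors(v, hs)[0] == pytest.approx(-0.4)

    def test_small_heterozygous_effect(self):
        v = make_variant([0.0, -0.037])
        hs = make_hapset([0, 1])
        assert assoc.build_threshold_free_predictors(v, hs)[0] == pytest.approx(
            -0.037
        )


class TestElasticNetCovarianceTest:
    def test_planted_effect_enters_first(self, rng):
        hits = first = 0
        null_p = []
        n_rep = 40
        for _ in range(n_rep):
            # orthonormal design: no signal leakage into null predictors
            Q, _ = np.linalg.qr(rng.normal(size=(200, 5)))
            X = pd.DataFrame(Q, columns=[f"v{j}" for j in range(5)])
            y = 5.0 * X["v0"].to_numpy() + rng.normal(0, 0.1, size=200)
            path = assoc.elastic_net_covariance_test(y, X)
            first_row = path[path["order"] == 1].iloc[0]
            first += first_row["variant"] == "v0"
            hits += first_row["variant"] == "v0" and first_row["p"] < 0.01
            null_p.extend(path[path["variant"] != "v0"]["p"].tolist())
        assert first == n_rep
        assert hits >= 0.9 * n_rep
        # each null predictor clears 0.05 at roughly its nominal rate
        assert np.mean(np.array(null_p) > 0.05) >= 0.9

    def test_identical_columns_finite(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"v1": x, "v2": x.copy()})
        y = x + rng.normal(0, 0.5, size=100)
        path = assoc.elastic_net_covariance_test(y, X)
        assert np.isfinite(path["beta"]).all()
        assert np.isfinite(path["T"]).all()

    def test_sigma_requires_enough_samples(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError, match="sigma"):
            assoc.elastic_net_covariance_test(rng.normal(size=5), X)

    def test_single_predictor_uses_ols(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        res = assoc.fit_gene_model_elastic_net(y, pd.DataFrame({"v": x}), gene="g")
        assert len(res.variant_stats) == 1
        assert res.variant_stats["p"].iloc[0] < 0.01

    def test_sign_consistency_with_thresholded(self, rng):
        """Both approaches agree on effect direction for a strong effect."""
        agree = 0
        n_rep = 30
        for _ in range(n_rep):
            dosage = rng.binomial(2, 0.3, size=150).astype(float)
            summed = -0.8 * dosage  # canonical log FCA sum: low alleles negative
            y = 1.0 * summed + rng.normal(0, 0.4, size=150)
            thr = assoc.fit_gene_model_thresholded(
                y, pd.DataFrame({"v": dosage}), gene="g"
            )
            tf = assoc.fit_gene_model_elastic_net(
                y, pd.DataFrame({"v": summed}), gene="g"
            )
            s_thr = np.sign(thr.variant_stats["beta"].iloc[0])
            s_tf = np.sign(tf.variant_stats["beta"].iloc[0])
            agree += s_thr == -s_tf  # dosage is anti-correlated with summed score
        assert agree >= 0.95 * n_rep
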