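"""Synthetic cohort generator: construction guarantees and determinism."""

import numpy as np
import pandas as pd
import pytest

from affinityqtl.crm import variant_maf
from affinityqtl.io import (
    read_variant_panel,
    write_variant_panel,
)
from affinityqtl.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate_accessibility_fixture,
    generate_cohort,
    generate_expression,
    generate_pwms,
)


class TestGeneratePwms:
    def test_columns_sum_to_one(self):
        for pwm in generate_pwms(3, (6, 10), seed=7):
            np.testing.assert_allclose(pwm.freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_uniform_option(self):
        (pwm,) = generate_pwms(1, (4, 4), seed=1, force_uniform=True)
        assert (pwm.freqs == 0.25).all()

    def test_seed_determinism_bitwise(self):
        a = generate_pwms(3, (6, 10), seed=7, frac_second_pwm=0.5)
        b = generate_pwms(3, (6, 10), seed=7, frac_second_pwm=0.5)
        assert len(a) == len(b)
        for p, q in zip(a, b):
            assert p.motif_id == q.motif_id
            assert (p.freqs == q.freqs).all()

    def test_every_primary_motif_has_exact_zero(self):
        pwms = generate_pwms(4, (8, 12), seed=3)
        assert all((p.freqs == 0.0).any() for p in pwms)

    def test_second_pwm_fraction(self):
        pwms = generate_pwms(20, (6, 8), seed=5, frac_second_pwm=1.0)
        assert len(pwms) == 40

    def test_invalid_width_range_rejected(self):
        with pytest.raises(ValueError):
            generate_pwms(2, (3, 10), seed=0)
        with pytest.raises(ValueError):
            generate_pwms(2, (10, 4), seed=0)


@pytest.fixture(scope="module")
def cohort():
    cfg = SyntheticConfig(
        seed=3,
        n_individuals=50,
        n_crm_regions=15,
        genome_length=60_000,
        maf_range=(0.1, 0.4),
        n_planted_effects=3,
        n_null_genes=6,
    )
    return generate_cohort(cfg)


class TestGenerateCohort:
    def test_all_mafs_in_configured_range(self, cohort):
        for v in cohort.variants:
            assert 0.1 <= variant_maf(v.genotypes) <= 0.4

    def test_variants_match_reference(self, cohort):
        for v in cohort.variants:
            assert cohort.genome[v.start : v.end] == v.ref

    def test_empty_case(self):
        cfg = SyntheticConfig(
            seed=1, n_crm_regions=0, n_planted_effects=0, n_null_genes=2,
            genome_length=30_000,
        )
        c = generate_cohort(cfg)
        assert c.variants == [] and all(not reps for reps in c.peaks.values())

    def test_at_least_one_indel(self, cohort):
        assert any(v.is_indel for v in cohort.variants)

    def test_two_tss_bait_present(self, cohort):
        frag = cohort.config.fragment_length
        frags = cohort.tss["tss"] // frag
        counts = frags.value_counts()
        assert (counts >= 2).any()

    def test_interaction_scores_straddle_cutoff(self, cohort):
        s = cohort.interactions["score"]
        assert (s >= 5).any() and (s < 5).any()

    def test_reference_individual_homozygous_at_planted_variants(self, cohort):
        r = cohort.config.reference_individual
        planted_ids = {p.variant_id for p in cohort.truth.planted}
        for v in cohort.variants:
            if v.id in planted_ids:
                assert v.genotypes[2 * r] == 0 and v.genotypes[2 * r + 1] == 0

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_cohort(
                SyntheticConfig(seed=0, n_crm_regions=100, genome_length=20_000)
            )

    def test_byte_identical_determinism(self, cohort, tmp_path):
        cfg = cohort.config
        other = generate_cohort(cfg)
        assert other.genome == cohort.genome
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_variant_panel(cohort.variants, cohort.individuals, p1)
        write_variant_panel(other.variants, other.individuals, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(cohort.interactions, other.interactions)
        pd.testing.assert_frame_equal(cohort.tss, other.tss)

    def test_panel_round_trip_and_phase_required(self, cohort, tmp_path):
        path = tmp_path / "panel.vcf"
        write_variant_panel(cohort.variants, cohort.individuals, path)
        back = read_variant_panel(path)
        assert len(back) == len(cohort.variants)
        assert all(
            (a.genotypes == b.genotypes).all() and a.pos == b.pos
            for a, b in zip(back, cohort.variants)
        )
        bad = path.read_text().replace("|", "/", 1)
        path.write_text(bad)
        with pytest.raises(ValueError, match="phased"):
            read_variant_panel(path)


class TestGenerateExpression:
    def _truth(self):
        from affinityqtl.synthetic import PlantedEffect

        planted = (
            PlantedEffect("g1", "chr1", 0, 100, "T1", 1.0, "v1", "distal"),
        )
        return SyntheticTruth(
            planted=planted, null_genes=("n1", "n2"), unexpressed_genes=("n2",)
        )

    def test_noiseless_limit(self):
        truth = self._truth()
        x = np.linspace(-1, 1, 20)
        predictors = pd.DataFrame([x], index=["g1"], columns=range(20))
        counts, resid = generate_expression(truth, predictors, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(resid.loc["g1"].to_numpy(), x, atol=1e-12)

    def test_null_gene_variance_close_to_noise(self):
        truth = SyntheticTruth(planted=(), null_genes=("n1",))
        predictors = pd.DataFrame(columns=range(359))
        variances = []
        for seed in range(30):
            _, resid = generate_expression(truth, predictors, noise_sd=1.0, seed=seed)
            variances.append(resid.loc["n1"].var(ddof=1))
        # E[s^2] = 1 with SE ~ sqrt(2/(n-1)) per seed
        se = np.sqrt(2 / 358 / 30)
        assert abs(np.mean(variances) - 1.0) < 3 * se

    def test_unexpressed_gene_majority_zero(self):
        truth = self._truth()
        predictors = pd.DataFrame(
            [np.zeros(40)], index=["g1"], columns=range(40)
        )
        counts, _ = generate_expression(truth, predictors, noise_sd=0.5, seed=2)
        assert (counts.loc["n2"] == 0).mean() > 0.5
        assert (counts.loc["n1"] == 0).mean() <= 0.5

    def test_dimension_mismatch_rejected(self):
        truth = self._truth()
        predictors = pd.DataFrame(columns=[])
        with pytest.raises(ValueError):
            generate_expression(truth, predictors, noise_sd=0.5, seed=0)

    def test_counts_monotone_in_residuals(self):
        truth = self._truth()
        x = np.linspace(-2, 2, 30)
        predictors = pd.DataFrame([x], index=["g1"], columns=range(30))
        counts, resid = generate_expression(truth, predictors, noise_sd=0.0, seed=0)
        order = np.argsort(resid.loc["g1"].to_numpy())
        sorted_counts = counts.loc["g1"].to_numpy()[order]
        assert (np.diff(sorted_counts) >= 0).all()


class TestAccessibilityFixture:
    def _table(self, rng, n=30):
        starts = np.arange(n) * 2000
        return pd.DataFrame(
            {
                "crm_id": [f"c{i}" for i in range(n)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 300,
                "driver_effect": rng.uniform(0, 2, n),
            }
        )

    def test_windows_disjoint_and_100bp(self, rng):
        table = self._table(rng)
        wins = generate_accessibility_fixture(table, 60_000, seed=4)
        assert ((wins["end"] - wins["start"]) == 100).all()
        starts = np.sort(wins["start"].to_numpy())
        assert (np.diff(starts) >= 100).all()

    def test_graded_rates_increase_with_effect(self, rng):
        table = self._table(rng, n=400)
        hits_low = hits_high = 0
        for seed in range(20):
            wins = generate_accessibility_fixture(
                table, 800_000, seed=seed, frac_effect=0.8,
                frac_background=0.02, graded_scale=2.0,
            )
            win_starts = set(wins["start"] // 100)
            for row in table.itertuples():
                mid_tile = (row.start + row.end) // 2 // 100
                hit = mid_tile in win_starts
                if row.driver_effect > 1.5:
                    hits_high += hit
                elif row.driver_effect < 0.5:
                    hits_low += hit
        assert hits_high > hits_low
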