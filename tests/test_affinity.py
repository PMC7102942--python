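"""TRAP affinity, GEV background normalization and log FCA."""

import math

import numpy as np
import pytest
from scipy.stats import genextreme

from affinityqtl.affinity import (
    GEVBackground,
    LNR0_INTERCEPT,
    LNR0_SLOPE,
    STANDARD_LENGTHS,
    build_affinity_atlas,
    fit_gev_scores,
    log_fca,
    nearest_standard_length,
    normalize_affinity,
    pool_tf_logfca,
    resize_sequence,
    trap_affinity,
    trap_affinity_naive,
)
from affinityqtl.crm import CRM, GenomicInterval, VariantRecord, enumerate_haplotypes
from affinityqtl.pwm import PWM


def uniform_pwm(width=4):
    return PWM("t", "m", np.full((4, width), 0.25))


def sharp_pwm():
    # consensus ACGT; column 2 forbids T entirely
    freqs = np.array(
        [
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.2, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.1, 0.0, 0.7],
        ]
    )
    return PWM("t", "m", freqs)


class TestTrap:
    def test_consensus_hand_value(self):
        """Single-placement consensus: p = R0/(1+R0) plus the revcomp term."""
        pwm = sharp_pwm()
        seq = "ACGT"
        ln_r0 = LNR0_SLOPE * 4 + LNR0_INTERCEPT
        r0 = math.exp(ln_r0)
        fwd = r0 / (1 + r0)
        # reverse complement of ACGT is ACGT: both strands see the consensus
        assert trap_affinity(seq, pwm) == pytest.approx(2 * fwd, rel=1e-12)

    def test_zero_frequency_voids_placement(self):
        pwm = sharp_pwm()
        # T at the zero-frequency cell (column 2) voids the only placement
        assert trap_affinity("ACTT", pwm) == pytest.approx(
            trap_affinity_naive("ACTT", pwm), rel=1e-12
        )
        energy_free = trap_affinity("ACTT", pwm)
        # forward placement is voided; only the revcomp placement contributes
        assert energy_free < trap_affinity("ACGT", pwm)

    def test_strand_symmetry(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            freqs = rng.dirichlet(np.ones(4), size=6).T
            pwm = PWM("t", "m", freqs)
            rc = seq.translate(comp)[::-1]
            assert trap_affinity(seq, pwm) == pytest.approx(
                trap_affinity(rc, pwm), rel=1e-9
            )

    def test_short_sequence_scores_zero(self):
        assert trap_affinity("AC", sharp_pwm()) == 0.0

    def test_ambiguous_bases_contribute_zero(self):
        pwm = uniform_pwm()
        with_n = trap_affinity("ACGTNACGT", pwm)
        # placements covering N are voided; the rest are unaffected
        assert with_n == pytest.approx(trap_affinity_naive("ACGTNACGT", pwm), rel=1e-9)
        assert with_n < trap_affinity("ACGTAACGT", pwm)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(25):
            width = int(rng.integers(4, 11))
            freqs = rng.dirichlet(np.ones(4), size=width).T
            pwm = PWM("t", "m", freqs)
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(width, 80))))
            fast = trap_affinity(seq, pwm)
            slow = trap_affinity_naive(seq, pwm)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_monotone_in_column_frequency(self, rng):
        """Replacing a base with a higher-frequency base never lowers affinity."""
        freqs = np.array(
            [
                [0.5, 0.4, 0.25, 0.1],
                [0.3, 0.3, 0.25, 0.2],
                [0.1, 0.2, 0.25, 0.3],
                [0.1, 0.1, 0.25, 0.4],
            ]
        )
        pwm = PWM("t", "m", freqs)
        seq = list("TTCA")
        base_aff = trap_affinity("".join(seq), pwm)
        seq[0] = "A"  # column 0: A has the highest frequency
        assert trap_affinity("".join(seq), pwm) >= base_aff


class TestGev:
    def test_parameter_recovery_from_known_gev(self, rng):
        true = (-0.1, 1.0, 0.5)  # scipy c = -xi for xi = 0.1
        draws = genextreme.rvs(*true, size=5000, random_state=rng)
        c, loc, scale = fit_gev_scores(draws)
        assert loc == pytest.approx(true[1], rel=0.1)
        assert scale == pytest.approx(true[2], rel=0.1)
        # the tail-censored estimator trades some shape efficiency for
        # tail calibration; require the shape within its sampling error
        # and the fitted upper-tail probabilities to agree closely
        assert c == pytest.approx(true[0], abs=0.05)
        for q in (0.01, 0.05, 0.1):
            x_q = genextreme.isf(q, *true)
            fitted_q = genextreme.sf(x_q, c, loc=loc, scale=scale)
            assert fitted_q == pytest.approx(q, abs=0.02)

    def test_degenerate_scores_raise(self):
        with pytest.raises(ValueError, match="identical"):
            fit_gev_scores(np.ones(100))

    def test_lengths_keyed_independently(self):
        bg = GEVBackground("m", {100: (0.1, 0.0, 1.0), 200: (0.2, 1.0, 2.0)})
        assert bg.lengths == [100, 200]
        assert bg.params[100] != bg.params[200]

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            GEVBackground("m", {100: (0.1, 0.0, -1.0)})

    def test_standard_lengths_match_protocol(self):
        assert STANDARD_LENGTHS == (
            40, 100, 200, 250, 300, 400, 500, 800, 1000, 2000, 3000,
        )


class TestNormalize:
    bg = GEVBackground("m", {200: (0.1, -3.0, 1.0)})

    def test_median_maps_to_half(self):
        median_log = genextreme.ppf(0.5, 0.1, loc=-3.0, scale=1.0)
        assert normalize_affinity(math.exp(median_log), 200, self.bg) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_large_affinity_tends_to_zero(self):
        assert normalize_affinity(1e12, 200, self.bg) == pytest.approx(0.0, abs=1e-6)

    def test_zero_affinity_is_weakest(self):
        assert normalize_affinity(0.0, 200, self.bg) == 1.0

    def test_nearest_length_selection(self):
        lengths = [100, 200, 250]
        assert nearest_standard_length(170, lengths) == 200
        assert nearest_standard_length(150, lengths) == 100  # tie -> smaller
        assert nearest_standard_length(5000, STANDARD_LENGTHS) == 3000

    def test_resize_cut_and_extend(self):
        genome = "ACGT" * 100
        assert len(resize_sequence(genome, 100, 300, 40)) == 40
        assert len(resize_sequence(genome, 100, 140, 200)) == 200
        # central cut keeps the midpoint
        cut = resize_sequence(genome, 100, 300, 40)
        assert cut == genome[180:220]


class TestLogFca:
    def test_identity_haplotype(self):
        assert log_fca(0.01, 0.01, 1e-6) == 0.0

    def test_printed_formula(self):
        assert log_fca(0.01, 0.001, 1e-6) == pytest.approx(1.0)

    def test_zero_substitution(self):
        assert log_fca(0.0, 1e-4, 1e-6) == pytest.approx(-2.0)

    def test_zero_floor_rejected(self):
        with pytest.raises(ValueError):
            log_fca(0.01, 0.01, 0.0)

    def test_monotone_in_a_alt(self):
        vals = [log_fca(a, 0.01, 1e-6) for a in (0.0, 1e-5, 1e-3, 0.1, 1.0)]
        assert vals == sorted(vals)

    def test_pool_median(self):
        assert pool_tf_logfca({"m1": 0.4}) == 0.4
        assert pool_tf_logfca({"m1": -1.0, "m2": 0.0, "m3": 2.0}) == 0.0
        assert pool_tf_logfca({"m1": 1.0, "m2": 3.0}) == 2.0
        with pytest.raises(ValueError):
            pool_tf_logfca({})


class TestAtlas:
    def _setup(self, seq, variants, bg_params=(-0.2, -6.0, 1.0)):
        crm = CRM(
            id="crm_x",
            interval=GenomicInterval("chr1", 0, len(seq)),
            bound_tfs=frozenset({"t"}),
            reference_sequence=seq,
        )
        hs = enumerate_haplotypes(crm, variants, n_chromosomes=4)
        pwm = sharp_pwm()
        bg = GEVBackground("m", {40: bg_params, 100: bg_params})
        return crm, hs, {"t": [pwm]}, {"m": bg}

    def test_invariant_crm_all_zero(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        crm, hs, pwms, bgs = self._setup(seq, [])
        atlas = build_affinity_atlas([crm], {crm.id: hs}, pwms, bgs)
        assert len(atlas) == 1
        assert atlas[0].invariant
        assert all(v == 0.0 for v in atlas[0].log_fca)

    def test_weak_reference_allele_excluded(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        # background centred far above any achievable score -> A ~ 1
        crm, hs, pwms, bgs = self._setup(seq, [], bg_params=(-0.2, 50.0, 1.0))
        atlas = build_affinity_atlas([crm], {crm.id: hs}, pwms, bgs)
        assert atlas == []

    def test_disrupting_snp_changes_logfca(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        # substitute the forbidden base T at a column-2 position (index 2)
        v = VariantRecord("v", "chr1", 3, "G", "T", np.array([0, 0, 1, 1]))
        crm, hs, pwms, bgs = self._setup(seq, [v])
        atlas = build_affinity_atlas([crm], {crm.id: hs}, pwms, bgs)
        assert len(atlas) == 1
        av = atlas[0]
        assert av.log_fca[av.ref_best_haplotype] == 0.0
        assert av.max_abs_logfca > 0.0
        # canonical convention: the disrupted haplotype scores negative
        alt_idx = 1 - av.ref_best_haplotype
        assert av.log_fca[alt_idx] < 0.0

    def test_tf_without_motif_skipped(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        crm, hs, pwms, bgs = self._setup(seq, [])
        crm2 = CRM(
            id="crm_y",
            interval=crm.interval,
            bound_tfs=frozenset({"nomotif"}),
            reference_sequence=seq,
        )
        atlas = build_affinity_atlas(
            [crm, crm2], {crm.id: hs, "crm_y": hs}, pwms, bgs
        )
        assert {a.crm_id for a in atlas} == {"crm_x"}
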