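"""Promoter windows, PWM scanning, CRM scoring and rank aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirddr.ingest import ConfigurationError, InputError
from mirddr.motifs import (
    PWM,
    aggregate_order_statistics,
    aggregate_ranking,
    calibrated_q,
    crm_score,
    delineate_promoter,
    estimate_background,
    rank_species,
    scan_pwm,
)

UNIFORM_PWM = PWM("uniform", np.full((4, 8), 0.25))


def sharp_pwm(consensus: str, p: float = 0.85, motif_id: str = "sharp") -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[idx[b], j] = p
    return PWM(motif_id, m)


class TestDelineatePromoter:
    def test_intergenic_window_plus_strand(self):
        assert delineate_promoter(100_000, "intergenic_anchor", "+") == (95_000, 100_500)

    def test_intergenic_window_minus_strand_is_mirrored(self):
        assert delineate_promoter(100_000, "intergenic_anchor", "-",
                                  contig_length=1_000_000) == (99_500, 105_000)

    def test_host_tss_and_intragenic_windows(self):
        assert delineate_promoter(50_000, "host_tss", "+") == (46_000, 52_000)
        assert delineate_promoter(50_000, "intragenic_anchor", "+") == (46_500, 49_500)
        assert delineate_promoter(50_000, "intragenic_anchor", "-") == (50_500, 53_500)

    def test_window_clipped_at_contig_bounds(self):
        start, end = delineate_promoter(2_000, "intergenic_anchor", "+",
                                        contig_length=10_000)
        assert (start, end) == (0, 2_500)

    def test_anchor_beyond_contig_is_an_error(self):
        with pytest.raises(InputError):
            delineate_promoter(11_000, "host_tss", "+", contig_length=10_000)


class TestScanPwm:
    def test_uniform_pwm_on_uniform_background_scores_zero(self):
        scores = scan_pwm("ACGTACGTACGTACGT", UNIFORM_PWM)
        assert np.allclose(scores, 0.0)

    def test_consensus_site_is_argmax(self):
        pwm = sharp_pwm("ACGTTGCA")
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        k = 25
        seq = seq[:k] + "ACGTTGCA" + seq[k + 8:]
        scores = scan_pwm(seq, pwm)
        assert int(np.argmax(scores[:, 0])) == k

    def test_matches_naive_per_position_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        m = rng.dirichlet(np.ones(4), size=6).T  # random valid PWM, L=6
        pwm = PWM("rand", m)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        scores = scan_pwm(seq, pwm, bg)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i in range(len(seq) - 6 + 1):
            fwd = sum(math.log2(m[idx[b], j] / bg[idx[b]])
                      for j, b in enumerate(seq[i:i + 6]))
            rc = "".join(comp[b] for b in reversed(seq[i:i + 6]))
            rev = sum(math.log2(m[idx[b], j] / bg[idx[b]])
                      for j, b in enumerate(rc))
            assert scores[i, 0] == pytest.approx(fwd, abs=1e-12)
            assert scores[i, 1] == pytest.approx(rev, abs=1e-12)

    def test_n_windows_score_minus_infinity(self):
        scores = scan_pwm("ACGTNCGTACGTACGT", UNIFORM_PWM)
        assert np.isneginf(scores[0, 0]) and np.isfinite(scores[8, 0])

    def test_invalid_alphabet_is_an_error(self):
        with pytest.raises(InputError):
            scan_pwm("ACGU" * 4, UNIFORM_PWM)


class TestCrmScore:
    BG = np.full(4, 0.25)

    def test_region_with_no_positive_hits_scores_zero(self):
        pwm = sharp_pwm("AAAACCCC")
        assert crm_score("GTGTGTGTGTGTGTGTGTGT", [pwm], self.BG) == 0.0

    def test_single_planted_consensus_scores_its_log_odds(self):
        pwm = sharp_pwm("ACGTTGCA")
        site_score = float(np.log2(pwm.matrix.max(axis=0) / 0.25).sum())
        seq = "G" * 20 + "ACGTTGCA" + "G" * 20
        # poly-G background contributes no competing positive hits
        assert crm_score(seq, [pwm], self.BG) == pytest.approx(site_score)

    def test_three_nonoverlapping_sites_sum_and_match_exhaustive_oracle(self):
        pwm = sharp_pwm("ACGTTGCA")
        seq = ("G" * 10 + "ACGTTGCA" + "G" * 12 + "ACGTTGCA" + "G" * 12
               + "ACGTTGCA" + "G" * 10)
        got = crm_score(seq, [pwm], self.BG)
        # oracle: exhaustive search over all subsets of positive hits
        scores = scan_pwm(seq, pwm, self.BG)
        hits = [(i, i + 8, s)
                for strand in (0, 1)
                for i, s in enumerate(scores[:, strand]) if s > 0]
        best = 0.0
        for r in range(1, len(hits) + 1):
            for combo in itertools.combinations(hits, r):
                intervals = sorted((h[0], h[1]) for h in combo)
                if all(b[0] >= a[1] for a, b in zip(intervals, intervals[1:])):
                    best = max(best, sum(h[2] for h in combo))
        assert got == pytest.approx(best, abs=1e-9)
        site = float(np.log2(pwm.matrix.max(axis=0) / 0.25).sum())
        assert got == pytest.approx(3 * site, abs=1e-9)

    def test_monotone_in_number_of_planted_sites(self):
        pwm = sharp_pwm("ACGTTGCA")
        rng = np.random.default_rng(3)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        prev = None
        for n_sites in range(4):
            seq = list(base)
            for s in range(n_sites):
                pos = 30 + 40 * s
                seq[pos:pos + 8] = "ACGTTGCA"
            score = crm_score("".join(seq), [pwm], self.BG, window=200)
            if prev is not None:
                assert score >= prev - 1e-9
            prev = score

    def test_empty_pwm_list_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            crm_score("ACGT" * 10, [], self.BG)


class TestRankSpecies:
    def test_best_of_ten_gets_one_tenth(self):
        scores = {f"f{k}": float(10 - k) for k in range(10)}
        ranks = rank_species(scores)
        assert ranks["f0"] == pytest.approx(0.1)

    def test_all_equal_scores_share_mean_rank(self):
        n = 6
        ranks = rank_species({f"f{k}": 1.0 for k in range(n)})
        assert np.allclose(ranks, (n + 1) / (2 * n))

    def test_ranks_are_monotone_inverse_of_scores(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=30),
                           index=[f"f{k}" for k in range(30)])
        ranks = rank_species(scores)
        ordered = scores.sort_values(ascending=False).index
        assert list(ranks[ordered]) == sorted(ranks)


class TestAggregateOrderStatistics:
    def test_single_rank_is_its_own_probability(self):
        assert aggregate_order_statistics([0.3]) == pytest.approx(0.3)

    def test_all_worst_ranks_give_q_one(self):
        assert aggregate_order_statistics([1.0] * 7) == pytest.approx(1.0)

    def test_two_species_closed_form(self):
        # P(min of two uniforms <= 0.5) = 1 - 0.25
        assert aggregate_order_statistics([0.5, 1.0]) == pytest.approx(0.75)

    def test_out_of_range_ranks_rejected(self):
        with pytest.raises(InputError):
            aggregate_order_statistics([0.0, 0.5])
        with pytest.raises(InputError):
            aggregate_order_statistics([0.5, 1.2])

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_matches_monte_carlo_within_three_se(self, n):
        rng = np.random.default_rng(40 + n)
        for _ in range(3):
            r = np.sort(rng.uniform(0.05, 1.0, n))
            q = aggregate_order_statistics(r)
            draws = np.sort(rng.uniform(size=(100_000, n)), axis=1)
            hit = np.all(draws <= r, axis=1)
            mc, se = hit.mean(), hit.std() / np.sqrt(len(hit))
            assert abs(q - mc) <= max(3 * se, 1e-4)

    def test_calibration_is_monotone_and_bounded(self):
        qs = [calibrated_q(v, 10) for v in (1e-6, 1e-3, 0.05, 0.5, 1.0)]
        assert qs == sorted(qs)
        assert 0 < qs[0] and qs[-1] <= 1.0


class TestAggregateRanking:
    def test_missing_species_treated_as_worst_rank(self):
        per = pd.DataFrame({
            "sp1": {"a": 5.0, "b": 1.0, "c": 0.5},
            "sp2": {"a": 4.0, "b": np.nan, "c": 1.0},
        })
        out = aggregate_ranking(per, calibrate=False)
        assert out.loc["a", "rank"] == 0
        # a is best in sp1 (rank 1/3 of 3) and in sp2 (rank 1/2 of 2)
        assert out.loc["a", "final_score"] == pytest.approx(
            -np.log(aggregate_order_statistics([1 / 3, 1 / 2])))
        # b missing in sp2 -> rank vector (2/3 in sp1, 1.0 in sp2)
        assert out.loc["b", "raw_q"] == pytest.approx(
            aggregate_order_statistics([2 / 3, 1.0]))

    def test_ties_break_lexicographically(self):
        per = pd.DataFrame({"sp1": {"zeta": 1.0, "alpha": 1.0, "mid": 1.0}})
        out = aggregate_ranking(per)
        assert list(out.index) == ["alpha", "mid", "zeta"]
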