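"""Robustness filter, redundancy rules, kinetic clusters, p53 dependence."""

import numpy as np
import pandas as pd
import pytest

from mirddr.ingest import InputError, MatureMiRNA
from mirddr.selection import (
    assign_clusters,
    compare_sets,
    dependence_fractions,
    p53_dependence,
    resolve_redundancy,
    robust_filter,
    timing_chisq,
)


def records_frame(rows):
    return pd.DataFrame(
        rows, columns=["mirna", "cell_line", "time_h", "M", "significant"])


class TestRobustFilter:
    def test_consistent_trend_in_two_cell_lines_is_retained(self):
        # let-7a-3p-like: positive M at both times, significant in both lines
        rows = [
            ("let7", "MCF", 4, 1.55, True), ("let7", "MCF", 24, 0.49, False),
            ("let7", "HCT", 4, 0.89, True), ("let7", "HCT", 24, 0.50, False),
        ]
        call = robust_filter(records_frame(rows), "induced")
        assert call.members == {"let7"}
        assert call.provenance["let7"]["MCF"]["trend"] is True

    def test_sign_flip_fails_trend_in_that_cell_line(self):
        # miR-139-5p-like in MCF: +1.00 then -1.00; HCT trend holds
        rows = [
            ("m139", "MCF", 4, 1.00, True), ("m139", "MCF", 24, -1.00, False),
            ("m139", "HCT", 4, 0.40, False), ("m139", "HCT", 24, 1.23, True),
        ]
        call = robust_filter(records_frame(rows), "induced")
        assert call.provenance["m139"]["MCF"]["trend"] is False
        # only one supporting cell line and no replicate support -> rejected
        assert call.members == set()

    def test_two_replicates_substitute_for_second_cell_line(self):
        rows = [
            ("m", "MCF", 4, 1.2, True), ("m", "MCF", 24, 0.8, True),
            ("m", "HCT", 4, -0.1, False), ("m", "HCT", 24, 0.2, False),
        ]
        per_rep = pd.DataFrame({
            "mirna": ["m", "m"], "cell_line": ["MCF", "MCF"],
            "replicate": [1, 2], "time_h": [4, 4],
            "M": [1.1, 1.3], "significant": [True, True],
        })
        no_rep = robust_filter(records_frame(rows), "induced")
        with_rep = robust_filter(records_frame(rows), "induced",
                                 per_replicate=per_rep)
        assert no_rep.members == set()
        assert with_rep.members == {"m"}

    def test_all_null_table_selects_nothing(self):
        rows = [
            (f"m{k}", cl, t, 0.01 * (k % 3 - 1), False)
            for k in range(10) for cl in ("MCF", "HCT") for t in (4, 24)
        ]
        call = robust_filter(records_frame(rows), "induced")
        assert call.members == set()

    def test_direction_filters_sign(self):
        rows = [
            ("up", "MCF", 4, 1.5, True), ("up", "MCF", 24, 0.9, True),
            ("up", "HCT", 4, 1.1, True), ("up", "HCT", 24, 0.8, True),
            ("down", "MCF", 4, -1.5, True), ("down", "MCF", 24, -0.9, True),
            ("down", "HCT", 4, -1.1, True), ("down", "HCT", 24, -0.8, True),
        ]
        assert robust_filter(records_frame(rows), "induced").members == {"up"}
        assert robust_filter(records_frame(rows), "repressed").members == {"down"}


class TestResolveRedundancy:
    @pytest.fixture
    def arm_pair_reference(self):
        return [
            MatureMiRNA("mir-486-5p", "ACGTACGTACGTACGTACGT", "mir-486", "5p"),
            MatureMiRNA("mir-486-3p", "TTGCAGGCAGTGCAAGTCTA", "mir-486", "3p"),
            MatureMiRNA("mir-365a-3p", "GGATTCCAGGCTTACGATCC", "mir-365a", "3p"),
            MatureMiRNA("mir-365b-3p", "GGATTCCAGGCTTACGATCC", "mir-365b", "3p"),
        ]

    def test_star_arm_removed_by_coverage(self, arm_pair_reference):
        kept, removed = resolve_redundancy(
            {"mir-486-5p", "mir-486-3p"}, arm_pair_reference,
            {"mir-486-5p": 5000, "mir-486-3p": 200})
        assert kept == {"mir-486-5p"}
        assert removed == [("mir-486-3p", "star_arm")]

    def test_identical_sequences_collapse_to_one(self, arm_pair_reference):
        kept, removed = resolve_redundancy(
            {"mir-365a-3p", "mir-365b-3p"}, arm_pair_reference,
            {"mir-365a-3p": 900, "mir-365b-3p": 900})
        assert kept == {"mir-365a-3p"}  # lexicographically smallest id
        assert removed == [("mir-365b-3p", "identical_sequence")]

    def test_missing_coverage_is_an_error(self, arm_pair_reference):
        with pytest.raises(InputError):
            resolve_redundancy({"mir-486-5p", "mir-486-3p"},
                               arm_pair_reference, {"mir-486-5p": 10})


class TestAssignClusters:
    def _frame(self, m4, m24, mirna="m"):
        return pd.DataFrame({"mirna": [mirna, mirna], "time_h": [4, 24],
                             "M": [m4, m24]})

    def test_early_induced_peak(self):
        out = assign_clusters(self._frame(2.0, 0.5), preset="mcf10a")
        assert out.loc["m", "label"] == "A"
        assert out.loc["m", "peak_time"] == 4

    def test_late_repressed_peak(self):
        out = assign_clusters(self._frame(-0.1, -1.5), preset="mcf10a")
        assert out.loc["m", "label"] == "D"

    def test_conventions_swap_induced_labels(self):
        early = self._frame(2.0, 0.5)
        assert assign_clusters(early, "mcf10a").loc["m", "label"] == "A"
        assert assign_clusters(early, "hct116").loc["m", "label"] == "B"

    def test_tie_on_magnitude_goes_to_late_time(self):
        out = assign_clusters(self._frame(1.0, -1.0))
        assert out.loc["m", "peak_time"] == 24
        assert bool(out.loc["m", "tie"])

    def test_assignment_is_a_partition(self):
        rng = np.random.default_rng(4)
        rows = []
        for k in range(40):
            rows.append({"mirna": f"m{k}", "time_h": 4, "M": rng.normal()})
            rows.append({"mirna": f"m{k}", "time_h": 24, "M": rng.normal()})
        out = assign_clusters(pd.DataFrame(rows))
        assert len(out) == 40
        assert set(out["label"]) <= {"A", "B", "C", "D"}


class TestCompareSets:
    def test_identical_sets(self):
        v = compare_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        assert v["union"] == 2 and v["intersections"][("a", "b")] == 2

    def test_disjoint_sets_sum(self):
        a = {f"m{k}" for k in range(88)}
        b = {f"n{k}" for k in range(62)}
        v = compare_sets({"a": a, "b": b})
        assert v["union"] == 150 and v["intersections"][("a", "b")] == 0

    def test_inclusion_exclusion_holds_exactly(self):
        rng = np.random.default_rng(9)
        universe = [f"m{k}" for k in range(200)]
        a = {m for m in universe if rng.random() < 0.4}
        b = {m for m in universe if rng.random() < 0.3}
        v = compare_sets({"a": a, "b": b})
        assert v["union"] == (v["sizes"]["a"] + v["sizes"]["b"]
                              - v["intersections"][("a", "b")])


class TestTimingChisq:
    def test_homogeneous_table_gives_zero(self):
        stat, p = timing_chisq([[10, 10], [10, 10]])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a, b, c, d = 23, 24, 3, 51
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = timing_chisq([[a, b], [c, d]])
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_row_swap_invariance(self):
        s1, p1 = timing_chisq([[23, 24], [3, 51]])
        s2, p2 = timing_chisq([[3, 51], [23, 24]])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(InputError):
            timing_chisq([[0, 0], [5, 3]])


class TestP53Dependence:
    def _frame(self, mirna, M, significant):
        return pd.DataFrame({
            "mirna": [mirna], "time_h": [24], "M": [M],
            "significant": [significant]})

    def test_lost_induction_in_ko_is_dependent(self):
        calls = p53_dependence(self._frame("m", 2.0, True),
                               self._frame("m", 0.1, False))
        assert calls["m"] == "p53_dependent"

    def test_retained_induction_in_ko_is_independent(self):
        calls = p53_dependence(self._frame("m", 2.0, True),
                               self._frame("m", 1.8, True))
        assert calls["m"] == "p53_independent"

    def test_missing_ko_data_is_indeterminate(self):
        calls = p53_dependence(self._frame("m", 2.0, True),
                               self._frame("other", 1.0, False))
        assert calls["m"] == "indeterminate"

    def test_fractions_per_cluster(self):
        wt = pd.concat([self._frame("m1", 2.0, True),
                        self._frame("m2", 1.5, True)], ignore_index=True)
        ko = pd.concat([self._frame("m1", 0.05, False),
                        self._frame("m2", 1.4, True)], ignore_index=True)
        calls = p53_dependence(wt, ko)
        clusters = pd.DataFrame({"label": ["A", "A"]}, index=["m1", "m2"])
        fracs = dependence_fractions(calls, clusters)
        assert fracs.loc["A", "fraction_dependent"] == pytest.approx(0.5)
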