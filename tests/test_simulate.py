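"""Determinism, construction fidelity and bookkeeping of the generator."""

import hashlib

import numpy as np
import pytest

from mirddr.context import label_loci
from mirddr.ingest import InputError, filter_reads, quantify_exact, trim_adapter
from mirddr.motifs import crm_score, estimate_background
from mirddr.simulate import (
    GeometryConfig,
    MotifPlantConfig,
    SimulationConfig,
    SpikeConfig,
    demo_pwms,
    functional_representatives,
    simulate_annotation,
    simulate_counts,
    simulate_promoters,
    simulate_reads,
)

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

SMALL = SimulationConfig(
    seed=5, n_mirnas=60, geometry=GeometryConfig(
        intragenic_single=20, intragenic_clusters=4, intragenic_cluster_size=3,
        intergenic_single=22, intergenic_clusters=2, intergenic_cluster_size=3),
    spikes=SpikeConfig(n_per_cluster=4), library_size_mean=20_000,
    motif_plant=MotifPlantConfig(n_planted=8, promoter_length=400),
)


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        t1, _ = simulate_counts(SMALL)
        t2, _ = simulate_counts(SMALL)
        assert t1.counts.equals(t2.counts)

    def test_distinct_seeds_give_distinct_tables(self):
        import dataclasses
        t1, _ = simulate_counts(SMALL)
        t2, _ = simulate_counts(dataclasses.replace(SMALL, seed=6))
        h = lambda t: hashlib.sha256(t.counts.to_csv().encode()).hexdigest()
        assert h(t1) != h(t2)

    def test_fixed_seed_gives_identical_promoters(self):
        pwms = demo_pwms()
        r1, p1 = simulate_promoters(SMALL, pwms)
        r2, p2 = simulate_promoters(SMALL, pwms)
        assert r1 == r2 and p1 == p2


class TestCounts:
    def test_expected_fold_change_at_peak_is_construction_exact(self):
        _, truth = simulate_counts(SMALL)
        exp = truth.expected_merged
        m = truth.mirnas
        # spike ratio = 4 x the null compositional ratio (total-mass shift
        # and library-size draws affect every miRNA identically)
        null_ratio = (exp.loc[m["archetype"] == "null", "MCF10A_WT_t4h"].iloc[0]
                      / exp.loc[m["archetype"] == "null", "MCF10A_WT_t0h"].iloc[0])
        for mid in m.index[m["archetype"] == "A"]:
            ratio = exp.at[mid, "MCF10A_WT_t4h"] / exp.at[mid, "MCF10A_WT_t0h"]
            assert ratio == pytest.approx(4.0 * null_ratio, rel=1e-9)

    def test_ko_zeroes_p53_dependent_effects(self):
        _, truth = simulate_counts(SMALL)
        exp, m = truth.expected_merged, truth.mirnas
        dep = m.index[m["p53_dependent"] & (m["archetype"] == "A")]
        indep = m.index[~m["p53_dependent"] & (m["archetype"] == "A")]
        null_ratio = (exp.loc[m["archetype"] == "null", "HCT116_TP53KO_t4h"]
                      / exp.loc[m["archetype"] == "null", "HCT116_TP53KO_t0h"])
        for mid in dep:
            r = exp.at[mid, "HCT116_TP53KO_t4h"] / exp.at[mid, "HCT116_TP53KO_t0h"]
            assert r == pytest.approx(null_ratio.iloc[0], rel=1e-9)
        for mid in indep:
            r = exp.at[mid, "HCT116_TP53KO_t4h"] / exp.at[mid, "HCT116_TP53KO_t0h"]
            assert r > 2 * null_ratio.iloc[0]

    def test_library_sizes_equal_column_sums(self):
        table, _ = simulate_counts(SMALL)
        assert np.allclose(table.counts.sum(axis=0), table.library_sizes)

    def test_star_arm_baseline_below_functional_arm(self):
        _, truth = simulate_counts(SMALL)
        w = truth.mirnas["baseline_weight"]
        for i in range(SMALL.n_arm_pairs):
            five, three = truth.reference[2 * i], truth.reference[2 * i + 1]
            assert w[three.id] < w[five.id]

    def test_functional_representatives_collapse_redundancies(self):
        _, truth = simulate_counts(SMALL)
        special = [m.id for m in truth.reference[:8]]
        reps = functional_representatives(special, truth.reference)
        assert len(reps) == 4  # one per stem-loop / identical-sequence group
        assert all(r.endswith("-5p") or r.split("-")[2][-1] == "a"
                   for r in reps)

    def test_infeasible_geometry_is_an_error(self):
        with pytest.raises(InputError):
            SimulationConfig(n_mirnas=10, geometry=GeometryConfig.singles(9))


class TestReads:
    def test_round_trip_reproduces_counts_exactly(self):
        import dataclasses
        cfg = dataclasses.replace(
            SMALL, library_size_mean=2_000,
            cell_lines=(("MCF10A", "WT"),), times=(0, 4))
        table, truth = simulate_counts(cfg)
        reads = simulate_reads(table, truth.reference, ADAPTER, seed=1)
        # oracle: generator bookkeeping; identical matures receive the
        # summed counts of their sequence group
        seq_groups: dict[str, list[str]] = {}
        for m in truth.reference:
            seq_groups.setdefault(m.sequence, []).append(m.id)
        for sample in table.sample_ids:
            trimmed = [trim_adapter(r, ADAPTER) for r in reads[sample]]
            kept, _ = filter_reads([r for r in trimmed if r is not None])
            counts, unmatched, _ = quantify_exact(kept, truth.reference, sample)
            assert unmatched == 0
            for seq, ids in seq_groups.items():
                expected = int(table.counts.loc[ids, sample].sum())
                for mid in ids:
                    assert counts[mid] == expected

    def test_contaminants_are_removed_by_filters(self):
        import dataclasses
        cfg = dataclasses.replace(
            SMALL, library_size_mean=1_000,
            cell_lines=(("MCF10A", "WT"),), times=(0,))
        table, truth = simulate_counts(cfg)
        reads = simulate_reads(table, truth.reference, ADAPTER, seed=2,
                               contaminant_polyn_fraction=0.1,
                               contaminant_short_fraction=0.05)
        sample = table.sample_ids[0]
        trimmed = [trim_adapter(r, ADAPTER) for r in reads[sample]]
        kept, rejected = filter_reads([r for r in trimmed if r is not None])
        n_real = int(table.counts[sample].sum())
        assert rejected["complexity"] == round(0.1 * n_real)
        assert rejected["length"] == round(0.05 * n_real)
        assert len(kept) == n_real

    def test_empty_table_gives_empty_read_sets(self):
        table, truth = simulate_counts(SMALL)
        table.counts.iloc[:, :] = 0
        table.normalized = True  # bypass the raw-sum invariant
        reads = simulate_reads(table, truth.reference, ADAPTER)
        assert all(len(r) == 0 for r in reads.values())


class TestAnnotation:
    def test_classification_recovers_ground_truth_labels(self):
        loci, transcripts, truth_labels = simulate_annotation(SMALL)
        predicted = label_loci(loci, transcripts)
        assert set(predicted) == set(truth_labels)
        for mid, lab in predicted.items():
            assert lab.location == truth_labels[mid].location, mid
            assert lab.grouping == truth_labels[mid].grouping, mid
            assert lab.cluster_id == truth_labels[mid].cluster_id, mid

    def test_all_singles_geometry_has_no_clusters(self):
        cfg = SimulationConfig(seed=2, n_mirnas=30,
                               geometry=GeometryConfig.singles(30))
        loci, transcripts, labels = simulate_annotation(cfg)
        assert all(lab.grouping == "single" for lab in labels.values())

    def test_fixed_seed_gives_identical_annotation(self):
        a = simulate_annotation(SMALL)
        b = simulate_annotation(SMALL)
        assert a[0] == b[0] and a[1] == b[1]


class TestPromoters:
    def test_planted_features_outscore_unplanted_median(self):
        pwms = demo_pwms()
        regions, planted = simulate_promoters(SMALL, pwms)
        assert planted
        bg_of = {sp: estimate_background(feats.values())
                 for sp, feats in regions.items()}
        unplanted_median = {
            sp: np.median([crm_score(feats[f], pwms, bg_of[sp])
                           for f in list(feats)[:30] if f not in planted])
            for sp, feats in regions.items()
        }
        for fid, by_species in planted.items():
            for sp in by_species:
                score = crm_score(regions[sp][fid], pwms, bg_of[sp])
                assert score > unplanted_median[sp]

    def test_zero_species_coverage_plants_nothing(self):
        import dataclasses
        cfg = dataclasses.replace(
            SMALL, motif_plant=MotifPlantConfig(species_coverage=0))
        regions, planted = simulate_promoters(cfg, demo_pwms())
        assert all(not v for v in planted.values())

    def test_site_longer_than_region_is_an_error(self):
        import dataclasses
        cfg = dataclasses.replace(
            SMALL, motif_plant=MotifPlantConfig(promoter_length=8))
        with pytest.raises(InputError):
            simulate_promoters(cfg, demo_pwms(length=12))
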