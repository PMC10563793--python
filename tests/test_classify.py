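"""Pair- and gene-level duplicate classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from duplicability import classify
from duplicability.classify import (
    EXCLUDED,
    MIXED_TYPE,
    NO_MAJORITY,
    NO_PARALOGS,
    PRE_VERTEBRATE_ONLY,
    RETRO_PAIR,
    SINGLETON,
    SSD,
    WGD,
    ReferentialIntegrityError,
)
from duplicability.features import DEFAULT_NODE_AGES

from conftest import make_gene_table, make_pairs


def pair_rows(anchors):
    """Build pair rows linking chr1/chr2 segment genes at given positions."""
    return make_pairs(
        [(f"chr1_g{p1}", f"chr2_g{p2}", "Vertebrata") for p1, p2 in anchors]
    )


class TestCallOhnologPairs:
    def test_three_linking_pairs_within_gaps_are_called(self, two_segment_genes):
        # anchor gaps of 2 and 5 genes on both segments
        pairs = pair_rows([(0, 0), (3, 3), (9, 9)])
        called = classify.call_ohnolog_pairs(pairs, two_segment_genes)
        assert len(called) == 3

    def test_two_linking_pairs_are_not_enough(self, two_segment_genes):
        pairs = pair_rows([(0, 0), (1, 1)])
        assert classify.call_ohnolog_pairs(pairs, two_segment_genes) == set()

    def test_large_gap_splits_block_below_minimum(self, two_segment_genes):
        # brute-force derived: a 9-gene gap splits 4 pairs into 2+2, both < 3
        pairs = pair_rows([(0, 0), (1, 1), (11, 11), (12, 12)])
        assert classify.call_ohnolog_pairs(pairs, two_segment_genes) == set()

    def test_result_independent_of_row_order_and_member_order(self, two_segment_genes):
        pairs = pair_rows([(0, 0), (3, 3), (9, 9), (1, 11)])
        called = classify.call_ohnolog_pairs(pairs, two_segment_genes)
        shuffled = pairs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        swapped = shuffled.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        assert classify.call_ohnolog_pairs(shuffled, two_segment_genes) == called
        assert classify.call_ohnolog_pairs(swapped, two_segment_genes) == called

    def test_monotone_in_max_gap_and_min_block(self, two_segment_genes):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(2, 8)
            anchors = list(
                zip(rng.integers(0, 12, size=k), rng.integers(0, 12, size=k))
            )
            pairs = pair_rows(sorted(set(anchors)))
            base = classify.call_ohnolog_pairs(pairs, two_segment_genes, 3, 3)
            wider = classify.call_ohnolog_pairs(pairs, two_segment_genes, 3, 5)
            looser = classify.call_ohnolog_pairs(pairs, two_segment_genes, 2, 3)
            assert base <= wider
            assert base <= looser

    def test_missing_gene_raises_referential_error(self, two_segment_genes):
        pairs = make_pairs([("chr1_g0", "ghost", "Vertebrata")])
        with pytest.raises(ReferentialIntegrityError, match="ghost"):
            classify.call_ohnolog_pairs(pairs, two_segment_genes)


class TestMicrosynteny:
    def test_neighbour_pair_within_window(self, two_segment_genes):
        pairs = pair_rows([(10, 10), (12, 7)])  # offsets (+2, -3)
        assert classify.check_microsynteny(("chr1_g10", "chr2_g10"), pairs, two_segment_genes)

    def test_no_other_pairs(self, two_segment_genes):
        pairs = pair_rows([(10, 10)])
        assert not classify.check_microsynteny(("chr1_g10", "chr2_g10"), pairs, two_segment_genes)

    def test_neighbour_outside_window(self, two_segment_genes):
        pairs = pair_rows([(10, 10), (16, 11)])  # offsets (+6, +1)
        assert not classify.check_microsynteny(("chr1_g10", "chr2_g10"), pairs, two_segment_genes)


class TestRetroduplication:
    @pytest.mark.parametrize(
        "introns_a,introns_b,with_microsynteny,expected",
        [
            (0, 5, False, True),   # zero vs >= 3: retro regardless of synteny
            (0, 5, True, True),
            (0, 2, True, False),   # low-intron partner saved by microsynteny
            (0, 2, False, True),
            (2, 7, False, False),  # no zero-intron member
            (0, 0, False, True),   # both intronless, no local synteny
            (0, 0, True, False),
        ],
    )
    def test_rule_branches(self, introns_a, introns_b, with_microsynteny, expected):
        rows = [(f"chr1_g{p}", "chr1", p, 5, None) for p in range(10)]
        rows += [(f"chr2_g{p}", "chr2", p, 5, None) for p in range(10)]
        genes = make_gene_table(rows)
        genes.loc[genes.gene_id == "chr1_g5", "intron_count"] = introns_a
        genes.loc[genes.gene_id == "chr2_g5", "intron_count"] = introns_b
        pair_list = [("chr1_g5", "chr2_g5", "Mammalia")]
        if with_microsynteny:
            pair_list.append(("chr1_g6", "chr2_g4", "Mammalia"))
        pairs = make_pairs(pair_list)
        got = classify.detect_retroduplication(("chr1_g5", "chr2_g5"), genes, pairs)
        got_swapped = classify.detect_retroduplication(("chr2_g5", "chr1_g5"), genes, pairs)
        assert got == expected
        assert got_swapped == expected

    def test_missing_intron_count_raises(self):
        genes = make_gene_table([("a", "chr1", 0, np.nan, None), ("b", "chr1", 1, 3, None)])
        pairs = make_pairs([("a", "b", "Mammalia")])
        with pytest.raises(ValueError, match="'a'"):
            classify.detect_retroduplication(("a", "b"), genes, pairs)


class TestLabelPairs:
    def test_prevertebrate_beats_ohnolog_membership(self, two_segment_genes):
        pairs = pair_rows([(0, 0), (3, 3), (9, 9)])
        pairs.loc[0, "duplication_node"] = "Chordata"
        labeled = classify.label_pairs(pairs, two_segment_genes, DEFAULT_NODE_AGES)
        assert labeled.loc[0, "pair_label"] == classify.PAIR_PRE_VERTEBRATE
        assert set(labeled.loc[1:, "pair_label"]) <= {classify.PAIR_WGD, classify.PAIR_SSD}

    def test_called_pair_with_vertebrate_node_is_wgd(self, two_segment_genes):
        pairs = pair_rows([(0, 0), (3, 3), (9, 9)])
        labeled = classify.label_pairs(pairs, two_segment_genes, DEFAULT_NODE_AGES)
        assert (labeled["pair_label"] == classify.PAIR_WGD).all()

    def test_intronless_pair_outside_ohnolog_set_is_retro(self):
        genes = make_gene_table(
            [("a", "chr1", 0, 0, None), ("b", "chr2", 0, 5, None)]
        )
        pairs = make_pairs([("a", "b", "Primates")])
        labeled = classify.label_pairs(pairs, genes, DEFAULT_NODE_AGES)
        assert labeled.loc[0, "pair_label"] == classify.PAIR_RETRO

    def test_unknown_node_raises(self, two_segment_genes):
        pairs = pair_rows([(0, 0)])
        pairs.loc[0, "duplication_node"] = "Atlantis"
        with pytest.raises(KeyError, match="Atlantis"):
            classify.label_pairs(pairs, two_segment_genes, DEFAULT_NODE_AGES)


def labeled(rows):
    df = make_pairs([(a, b, "Vertebrata") for a, b, _ in rows])
    df["pair_label"] = [lab for _, _, lab in rows]
    return df


class TestGeneLabels:
    GENES = make_gene_table([(g, "chr1", i, 5, None) for i, g in enumerate("abcde")])

    def get(self, pairs, gene):
        out = classify.assign_gene_labels(pairs, self.GENES).set_index("gene_id")
        return out.loc[gene]

    def test_all_wgd_pairs(self):
        row = self.get(labeled([("a", "b", "WGD"), ("a", "c", "WGD")]), "a")
        assert row["label"] == WGD

    def test_mixed_types_excluded(self):
        row = self.get(labeled([("a", "b", "WGD"), ("a", "c", "SSD")]), "a")
        assert row["label"] == EXCLUDED and row["exclusion_reason"] == MIXED_TYPE

    def test_retro_exclusion_beats_mixed(self):
        row = self.get(
            labeled([("a", "b", "WGD"), ("a", "c", "SSD"), ("a", "d", "RETRO")]), "a"
        )
        assert row["exclusion_reason"] == RETRO_PAIR

    def test_prevertebrate_only_singleton(self):
        row = self.get(labeled([("a", "b", "PRE_VERTEBRATE")]), "a")
        assert row["label"] == SINGLETON
        assert row["singleton_subtype"] == PRE_VERTEBRATE_ONLY

    def test_unpaired_gene_is_singleton_without_paralogs(self):
        row = self.get(labeled([("a", "b", "WGD")]), "e")
        assert row["label"] == SINGLETON and row["singleton_subtype"] == NO_PARALOGS


class TestMajorityVote:
    def frame(self, label, reason=None, subtype=None):
        return pd.DataFrame(
            {
                "gene_id": ["g1"],
                "label": [label],
                "exclusion_reason": [reason],
                "singleton_subtype": [subtype],
            }
        )

    def test_two_to_one_majority(self):
        out = classify.majority_vote([self.frame(WGD), self.frame(WGD), self.frame(SSD)])
        assert out.loc[0, "label"] == WGD

    def test_unanimity(self):
        out = classify.majority_vote([self.frame(SSD)] * 3)
        assert out.loc[0, "label"] == SSD

    def test_three_way_disagreement_is_excluded(self):
        out = classify.majority_vote(
            [self.frame(WGD), self.frame(SSD), self.frame(SINGLETON)]
        )
        assert out.loc[0, "label"] == EXCLUDED
        assert out.loc[0, "exclusion_reason"] == NO_MAJORITY

    def test_mismatched_universes_raise(self):
        other = self.frame(WGD).assign(gene_id=["g2"])
        with pytest.raises(ReferentialIntegrityError):
            classify.majority_vote([self.frame(WGD), self.frame(WGD), other])


class TestPipeline:
    def test_empty_pair_table_gives_all_singletons(self, two_segment_genes):
        pairs = make_pairs([])
        res = classify.run_classification(
            two_segment_genes, pairs, {"a": None, "b": None, "c": None}, DEFAULT_NODE_AGES
        )
        assert (res.consensus["label"] == SINGLETON).all()

    def test_counts_partition_gene_universe(self, small_study, small_config):
        res = classify.run_classification(
            small_study["genes"],
            small_study["pairs"],
            {f"r{i}": s for i, s in enumerate(small_study["ohnolog_sets"])},
            small_config.node_age_table,
        )
        n = len(small_study["genes"])
        assert res.consensus["label"].notna().all()
        gene_rows = ["wgd_genes", "ssd_genes", "singleton_genes", "excluded_genes"]
        for col in res.summary.columns:
            assert res.summary.loc[gene_rows, col].sum() == n
        # presumed-SSD + retro + pre-vertebrate pairs partition the non-WGD pairs
        for col in [c for c in res.summary.columns if c != "consensus"]:
            assert (
                res.summary.loc["retroduplicated_pairs", col]
                + res.summary.loc["prevertebrate_pairs", col]
                + res.summary.loc["presumed_ssd_pairs", col]
                == res.summary.loc["non_wgd_pairs", col]
            )

    def test_three_planted_families_give_six_wgd_genes(self):
        from duplicability import simulate

        cfg = simulate.SimulationConfig(
            seed=1, n_chromosomes=2, genes_per_chromosome=40,
            n_ohnolog_families=3, n_ssd_families=2, n_retro_pairs=1,
            n_prevertebrate_pairs=0, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        res = classify.run_classification(
            genes, pairs, {"a": None, "b": None, "c": None}, cfg.node_age_table
        )
        assert res.summary.loc["wgd_genes", "consensus"] == 6
        cons = res.consensus.set_index("gene_id")["label"]
        expected = truth.true_class.map(
            lambda c: EXCLUDED if c == "RETRO_EXCLUDED" else c
        )
        assert (cons.reindex(expected.index) == expected).all()
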