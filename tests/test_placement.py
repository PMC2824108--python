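"""Hit filtering, insert-size estimation and clone placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacplace.model import AlignmentHit, EndRead
from bacplace.placement import (
    ALL_CATEGORIES,
    CloneEnds,
    InsertStats,
    candidate_spans,
    category_counts,
    classify_read_uniqueness,
    estimate_insert_stats,
    filter_hits,
    group_clones,
    parse_read_id,
    place_clone,
    place_clones,
    summarize_library,
)

from _oracles import enumerate_clone_category, filter_hits_loop, iterative_rejection_loop


def hit(read_id="r", chrom="1", start=0, end=700, strand="+", identity=99.0, alen=None):
    return AlignmentHit(read_id, chrom, start, end, strand, identity, alen or (end - start))


class TestFilterHits:
    def test_thresholds_are_strict(self):
        # exactly at the thresholds -> rejected on either axis
        at_span = hit(alen=100, identity=96.0)
        at_ident = hit(alen=500, identity=95.0)
        above = hit(alen=101, identity=95.1)
        assert filter_hits([at_span, at_ident, above]) == [above]

    def test_clearly_passing_hit_retained(self):
        h = hit(alen=500, identity=100.0)
        assert filter_hits([h]) == [h]

    def test_matches_loop_oracle_on_random_hits(self):
        rng = np.random.default_rng(42)
        hits = [
            hit(
                read_id=f"r{i}",
                alen=int(rng.integers(50, 800)),
                identity=float(rng.uniform(85, 100)),
            )
            for i in range(1000)
        ]
        assert filter_hits(hits) == filter_hits_loop(hits, 100, 95.0)

    @given(
        d_span=st.integers(min_value=-50, max_value=0),
        d_ident=st.floats(min_value=-5.0, max_value=0.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_loosening_thresholds_is_monotone(self, d_span, d_ident):
        rng = np.random.default_rng(7)
        hits = [
            hit(
                read_id=f"r{i}",
                alen=int(rng.integers(50, 300)),
                identity=float(rng.uniform(90, 100)),
            )
            for i in range(200)
        ]
        strict = filter_hits(hits, 100, 95.0)
        loose = filter_hits(hits, 100 + d_span, 95.0 + d_ident)
        assert set(strict) <= set(loose)


def test_read_uniqueness_classification():
    h1 = hit("r")
    h2 = hit("r", chrom="2")
    assert classify_read_uniqueness([h1]) == "unique"
    assert classify_read_uniqueness([h1, h2]) == "multiple"
    assert classify_read_uniqueness([]) == "unaligned"


def test_parse_read_id_default_and_custom():
    assert parse_read_id("bQ123A1.T7") == ("bQ123A1", "T7")
    assert parse_read_id("cl-7_SP6", r"^(?P<clone>.+)_(?P<end>\w+)$") == ("cl-7", "SP6")
    with pytest.raises(ValueError):
        parse_read_id("nodot", r"^(?P<clone>.+)\.(?P<end>[^.]+)$")


class TestEstimateInsertStats:
    def test_identical_spans_converge_immediately(self):
        stats = estimate_insert_stats([150_000] * 10)
        assert (stats.mean, stats.sd) == (150_000.0, 0.0)
        assert stats.iterations == 1
        assert stats.n_rejected == 0

    def test_planted_outliers_all_rejected(self):
        rng = np.random.default_rng(123)
        spans = list(rng.normal(150_000, 15_000, size=100)) + [1_000_000] * 5
        stats = estimate_insert_stats(spans)
        assert stats.n_rejected == 5
        assert abs(stats.mean - 150_000) / 150_000 < 0.02
        mean_o, sd_o, rejected_o = iterative_rejection_loop(spans)
        assert stats.mean == pytest.approx(mean_o)
        assert stats.sd == pytest.approx(sd_o)
        assert len(rejected_o) == stats.n_rejected
        assert all(r == 1_000_000 for r in rejected_o)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_insert_stats([150_000])

    def test_idempotent_on_accepted_set(self):
        rng = np.random.default_rng(9)
        spans = list(rng.normal(150_000, 15_000, size=200)) + [900_000, 10_000]
        first = estimate_insert_stats(spans)
        kept = [
            s for s in spans if first.lower <= s <= first.upper
        ]
        again = estimate_insert_stats(kept)
        assert again.n_rejected == 0
        assert again.mean == pytest.approx(first.mean)
        assert again.sd == pytest.approx(first.sd)

    def test_rejected_spans_never_readmitted(self):
        # A far outlier inflates the first-round SD; after its
        # rejection the window tightens but the outlier stays out.
        spans = [100, 100, 100, 100, 100, 100, 100, 100, 101, 99, 10_000]
        stats = estimate_insert_stats(spans)
        assert stats.n_rejected >= 1
        assert stats.upper < 10_000


STATS = InsertStats(mean=150_000, sd=15_000, n_used=100, n_rejected=0, iterations=1)


def clone_of(hits_by_end):
    c = CloneEnds("c1")
    for label, hs in hits_by_end.items():
        c.reads[label] = EndRead(f"c1.{label}", "c1", label, 700)
        c.hits[label] = hs
    return c


class TestPlaceUniquePairs:
    def test_inward_pair_within_bounds(self):
        c = clone_of(
            {
                "T7": [hit("c1.T7", start=1000, end=1700, strand="+")],
                "SP6": [hit("c1.SP6", start=149_300, end=150_000, strand="-")],
            }
        )
        p = place_clone(c, STATS)
        assert p.category == "unique_pair"
        assert (p.start, p.end, p.span) == (1000, 150_000, 149_000)
        assert p.orientation == "fwd_left" and p.strand == "+"

    def test_same_strand_rejected(self):
        c = clone_of(
            {
                "T7": [hit("c1.T7", start=1000, end=1700, strand="+")],
                "SP6": [hit("c1.SP6", start=149_300, end=150_000, strand="+")],
            }
        )
        assert place_clone(c, STATS).category == "same_strand_rejected"

    def test_outward_facing_rejected(self):
        # opposite strands but pointing away from each other
        c = clone_of(
            {
                "T7": [hit("c1.T7", start=149_300, end=150_000, strand="+")],
                "SP6": [hit("c1.SP6", start=1000, end=1700, strand="-")],
            }
        )
        assert place_clone(c, STATS).category == "same_strand_rejected"

    def test_unrealistic_distance_rejected(self):
        c = clone_of(
            {
                "T7": [hit("c1.T7", start=0, end=700, strand="+")],
                "SP6": [hit("c1.SP6", start=999_300, end=1_000_000, strand="-")],
            }
        )
        assert place_clone(c, STATS).category == "distance_rejected"

    def test_different_chromosomes_rejected(self):
        c = clone_of(
            {
                "T7": [hit("c1.T7", chrom="1", strand="+")],
                "SP6": [hit("c1.SP6", chrom="2", start=149_300, end=150_000, strand="-")],
            }
        )
        assert place_clone(c, STATS).category == "distance_rejected"


class TestRescue:
    def mate_hits(self):
        return [
            hit("c1.SP6", start=149_300, end=150_000, strand="-"),  # consistent
            hit("c1.SP6", chrom="2", start=149_300, end=150_000, strand="-"),
            hit("c1.SP6", start=500_000, end=500_700, strand="-"),  # too far
        ]

    def test_exactly_one_consistent_hit_rescues(self):
        c = clone_of(
            {"T7": [hit("c1.T7", start=1000, end=1700, strand="+")], "SP6": self.mate_hits()}
        )
        p = place_clone(c, STATS)
        assert p.category == "rescued"
        assert (p.start, p.end) == (1000, 150_000)

    def test_rescue_matches_exhaustive_enumeration(self):
        c = clone_of(
            {"T7": [hit("c1.T7", start=1000, end=1700, strand="+")], "SP6": self.mate_hits()}
        )
        expect = enumerate_clone_category(c.hits, STATS.lower, STATS.upper)
        assert place_clone(c, STATS).category == expect == "rescued"

    def test_only_same_strand_mates_leaves_single_end(self):
        mates = [
            hit("c1.SP6", start=149_300, end=150_000, strand="+"),
            hit("c1.SP6", start=120_000, end=120_700, strand="+"),
        ]
        c = clone_of({"T7": [hit("c1.T7", start=1000, end=1700, strand="+")], "SP6": mates})
        assert place_clone(c, STATS).category == "single_end"

    def test_two_consistent_mates_is_ambiguous(self):
        mates = [
            hit("c1.SP6", start=149_300, end=150_000, strand="-"),
            hit("c1.SP6", start=140_000, end=140_700, strand="-"),
        ]
        c = clone_of({"T7": [hit("c1.T7", start=1000, end=1700, strand="+")], "SP6": mates})
        assert place_clone(c, STATS).category == "ambiguous"


class TestSummarize:
    def test_empty_library_is_all_zero(self):
        s = summarize_library([], [], [])
        assert s.to_dict()["clones_placed_uniquely"] == 0
        assert s.reads_aligned == 0

    def test_simulated_counts_match_planted_mix(self, sim_bundle):
        s = summarize_library(
            sim_bundle["reads"], sim_bundle["filtered"], sim_bundle["placements"]
        )
        counts = category_counts(sim_bundle["placements"])
        assert s.clones_unique_pairs == counts["unique_pair"]
        assert s.clones_rescued == counts["rescued"]
        assert s.clones_placed_uniquely == counts["unique_pair"] + counts["rescued"]
        assert s.reads_unique + s.reads_multiple == s.reads_aligned
        assert s.clones_in_library == sim_bundle["config"].n_clones

    def test_inconsistent_counts_rejected(self):
        from bacplace.placement import LibrarySummary

        with pytest.raises(ValueError, match="inconsistent"):
            LibrarySummary(1, 2, 2, 1, 2, 2, 1, 0, 0)


class TestPipelineProperties:
    def test_every_clone_gets_exactly_one_category(self, sim_bundle):
        placements = sim_bundle["placements"]
        counts = category_counts(placements)
        assert sum(counts.values()) == len(placements) == sim_bundle["config"].n_clones
        assert set(counts) == set(ALL_CATEGORIES)

    def test_placement_matches_enumeration_oracle(self, sim_bundle):
        stats = sim_bundle["stats"]
        for clone, p in zip(sim_bundle["clones"], sim_bundle["placements"]):
            expect = enumerate_clone_category(clone.hits, stats.lower, stats.upper)
            assert p.category == expect, clone.clone_id

    def test_noise_free_simulation_recovers_all_clones(self):
        """With no multi-mapping and identical spans, every clone is a
        unique_pair at its true position."""
        from bacplace.simulate import (
            SimConfig,
            plant_variants,
            simulate_genome,
            simulate_hits,
            simulate_library,
        )

        cfg = SimConfig(
            seed=2,
            n_clones=80,
            insert_sd=0.0,
            substitution_rate=0.0,
            snp_rate=0.0,
            dip_rate=0.0,
            n_repeat_families=0,
            insertless_fraction=0.0,
        )
        seqs, genome, repeats = simulate_genome(cfg)
        sim_reads, truth = simulate_library(seqs, genome, cfg, [], repeats)
        hits, _ = simulate_hits(sim_reads, seqs, repeats)
        clones = group_clones([sr.read for sr in sim_reads], filter_hits(hits))
        stats = estimate_insert_stats(candidate_spans(clones))
        placements = place_clones(clones, stats)
        by_id = {t.clone_id: t for t in truth.clones}
        for p in placements:
            t = by_id[p.clone_id]
            assert p.category == "unique_pair"
            assert (p.chromosome, p.start, p.end) == (t.chromosome, t.start, t.end)
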