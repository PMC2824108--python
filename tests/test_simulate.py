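"""Simulator: determinism, genome structure, library statistics and
hit generation."""

import filecmp

import numpy as np
import pytest

from bacplace import io as bio
from bacplace.simulate import (
    SimConfig,
    emit_fixture_set,
    plant_variants,
    revcomp,
    simulate_genes,
    simulate_genome,
    simulate_hits,
    simulate_library,
)

FIXTURE_FILES = ("genome.fa", "genome.tsv", "reads.fa", "hits.tsv", "hits.sam", "truth.json")


def test_config_rejects_overlapping_end_reads():
    with pytest.raises(ValueError, match="twice the read length"):
        SimConfig(insert_mean=2_000.0, insert_sd=200.0, read_length_mean=700.0)


def test_config_rejects_bad_rates():
    with pytest.raises(ValueError, match="rates"):
        SimConfig(insertless_fraction=1.5)


class TestSimulateGenome:
    def test_repeat_copies_present_exact_copy_number(self):
        cfg = SimConfig(seed=4, n_repeat_families=2, repeat_copies=3, repeat_length=2_000)
        seqs, genome, copies = simulate_genome(cfg)
        by_family = {}
        for rc in copies:
            by_family.setdefault(rc.family, []).append(rc)
        assert set(by_family) == {0, 1}
        for fam, rcs in by_family.items():
            assert len(rcs) == 3
            texts = {seqs[rc.chromosome][rc.start : rc.end] for rc in rcs}
            assert len(texts) == 1  # identical copies

    def test_gc_fraction_near_half(self):
        cfg = SimConfig(seed=8, chromosome_lengths=(1_000_000,), include_x=False,
                        n_repeat_families=0)
        seqs, _, _ = simulate_genome(cfg)
        seq = seqs["1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # binomial 3-sigma bound around 0.5 at n = 1e6
        assert abs(gc - 0.5) < 3 * 0.5 / np.sqrt(len(seq))

    def test_index_matches_sequences(self):
        cfg = SimConfig(seed=4)
        seqs, genome, _ = simulate_genome(cfg)
        assert {e.name: e.length for e in genome} == {k: len(v) for k, v in seqs.items()}
        assert genome["X"].chrom_class == "X"


class TestSimulateLibrary:
    def test_zero_sd_spans_all_equal_mean(self):
        cfg = SimConfig(seed=6, n_clones=50, insert_sd=0.0, insertless_fraction=0.0,
                        n_repeat_families=0, snp_rate=0.0, dip_rate=0.0)
        seqs, genome, _ = simulate_genome(cfg)
        _, truth = simulate_library(seqs, genome, cfg, [], [])
        spans = {c.end - c.start for c in truth.clones}
        assert spans == {150_000}

    def test_span_mean_within_one_percent(self, sim_bundle):
        truth = sim_bundle["truth"]
        spans = [c.end - c.start for c in truth.clones if c.expected_category != "insertless"]
        assert len(spans) >= 400
        assert abs(np.mean(spans) - 150_000) / 150_000 < 0.01

    def test_insertless_fraction_emits_unmappable_reads(self):
        cfg = SimConfig(seed=9, n_clones=200, insertless_fraction=0.5, n_repeat_families=0)
        seqs, genome, _ = simulate_genome(cfg)
        sim_reads, truth = simulate_library(seqs, genome, cfg, [], [])
        insertless = {c.clone_id for c in truth.clones if c.expected_category == "insertless"}
        assert 60 <= len(insertless) <= 140  # ~Binomial(200, 0.5)
        for sr in sim_reads:
            assert (sr.chromosome is None) == (sr.read.clone_id in insertless)

    def test_x_sampling_weight_halves_x_density(self):
        cfg = SimConfig(
            seed=10, n_clones=2_000, x_weight=0.5, n_repeat_families=0,
            insertless_fraction=0.0,
        )
        seqs, genome, _ = simulate_genome(cfg)
        _, truth = simulate_library(seqs, genome, cfg, [], [])
        n_x = sum(1 for c in truth.clones if c.chromosome == "X")
        x_len = genome.total_length("X")
        aut_len = genome.total_length("autosome")
        n_aut = len(truth.clones) - n_x
        ratio = (n_x / x_len) / (n_aut / aut_len)
        assert 0.35 < ratio < 0.65  # ~0.5 with sampling noise

    def test_reads_come_from_opposite_strands_at_extremities(self):
        cfg = SimConfig(seed=12, n_clones=30, insertless_fraction=0.0, n_repeat_families=0,
                        snp_rate=0.0, dip_rate=0.0, substitution_rate=0.0)
        seqs, genome, _ = simulate_genome(cfg)
        sim_reads, truth = simulate_library(seqs, genome, cfg, [], [])
        by_clone = {}
        for sr in sim_reads:
            by_clone.setdefault(sr.read.clone_id, []).append(sr)
        for c in truth.clones:
            left, right = sorted(by_clone[c.clone_id], key=lambda s: s.ref_start)
            assert (left.strand, right.strand) == ("+", "-")
            assert left.ref_start == c.start
            assert right.ref_end == c.end
            # sequences match the reference at the recorded origin
            assert left.sequence == seqs[c.chromosome][left.ref_start : left.ref_end]
            assert right.sequence == revcomp(
                seqs[c.chromosome][right.ref_start : right.ref_end]
            )


class TestSimulateHits:
    def test_repeat_free_read_yields_one_hit(self):
        cfg = SimConfig(seed=13, n_clones=40, n_repeat_families=0, insertless_fraction=0.0)
        seqs, genome, reps = simulate_genome(cfg)
        sim_reads, _ = simulate_library(seqs, genome, cfg, [], reps)
        hits, _ = simulate_hits(sim_reads, seqs, reps)
        assert len(hits) == len(sim_reads)

    def test_read_inside_three_copy_repeat_yields_three_hits(self, sim_bundle):
        truth = sim_bundle["truth"]
        cfg = sim_bundle["config"]
        multi_reads = set()
        for sr in sim_bundle["sim_reads"]:
            for rc in sim_bundle["repeats"]:
                if (
                    rc.chromosome == sr.chromosome
                    and rc.start <= sr.ref_start
                    and sr.ref_end <= rc.end
                ):
                    multi_reads.add(sr.read.read_id)
        assert multi_reads  # the study conditions do induce multi-mapping
        per_read = {}
        for h in sim_bundle["hits"]:
            per_read[h.read_id] = per_read.get(h.read_id, 0) + 1
        for rid in multi_reads:
            assert per_read[rid] == cfg.repeat_copies

    def test_tabular_and_sam_load_identical_hits(self, clean_variant_bundle, sim_bundle,
                                                 tmp_path):
        d = clean_variant_bundle["dir"]
        gi = bio.load_genome(d / "genome.tsv")
        tab = bio.load_hits(d / "hits.tsv", "tabular", gi)
        sam = bio.load_hits(d / "hits.sam", "sam", gi)
        assert sorted(tab, key=lambda h: (h.read_id, h.chromosome, h.start)) == sorted(
            sam, key=lambda h: (h.read_id, h.chromosome, h.start)
        )


def test_fixture_set_is_byte_deterministic(tmp_path):
    cfg = SimConfig(seed=21, n_clones=40)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    emit_fixture_set(cfg, d1)
    emit_fixture_set(cfg, d2)
    for f in FIXTURE_FILES:
        assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f


def test_adding_clones_preserves_earlier_draws(tmp_path):
    """The per-clone random substreams mean a larger library extends,
    rather than reshuffles, a smaller one."""
    cfg_small = SimConfig(seed=22, n_clones=30)
    cfg_big = SimConfig(seed=22, n_clones=60)
    seqs, genome, reps = simulate_genome(cfg_small)
    plants = plant_variants(seqs, cfg_small)
    _, truth_small = simulate_library(seqs, genome, cfg_small, plants, reps)
    _, truth_big = simulate_library(seqs, genome, cfg_big, plants, reps)
    for a, b in zip(truth_small.clones, truth_big.clones):
        assert (a.clone_id, a.chromosome, a.start, a.end) == (
            b.clone_id,
            b.chromosome,
            b.start,
            b.end,
        )


def test_simulated_genes_fit_genome():
    cfg = SimConfig(seed=23)
    _, genome, _ = simulate_genome(cfg)
    genes = simulate_genes(genome, cfg)
    assert len(genes) == cfg.n_genes
    for g in genes:
        assert g.chromosome in genome
        assert 0 <= g.start < g.end <= genome.length(g.chromosome)
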