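import pytest

from bacplace.placement import (
    candidate_spans,
    estimate_insert_stats,
    filter_hits,
    group_clones,
    place_clones,
)
from bacplace.simulate import (
    SimConfig,
    plant_variants,
    simulate_genome,
    simulate_hits,
    simulate_library,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """One full simulated library at the default study conditions
    (~150 kb inserts, 500 clones, repeat families inducing genuine
    multi-mapping), carried through the whole placement pipeline."""
    cfg = SimConfig(seed=11, n_clones=500)
    seqs, genome, repeats = simulate_genome(cfg)
    plants = plant_variants(seqs, cfg)
    sim_reads, truth = simulate_library(seqs, genome, cfg, plants, repeats)
    hits, aligned = simulate_hits(sim_reads, seqs, repeats)
    filtered = filter_hits(hits)
    reads = [sr.read for sr in sim_reads]
    clones = group_clones(reads, filtered)
    stats = estimate_insert_stats(candidate_spans(clones))
    placements = place_clones(clones, stats)
    return {
        "config": cfg,
        "seqs": seqs,
        "genome": genome,
        "repeats": repeats,
        "plants": plants,
        "sim_reads": sim_reads,
        "truth": truth,
        "hits": hits,
        "aligned": aligned,
        "filtered": filtered,
        "reads": reads,
        "clones": clones,
        "stats": stats,
        "placements": placements,
    }


@pytest.fixture(scope="session")
def clean_variant_bundle(tmp_path_factory):
    """Error-free, repeat-free fixture set on disk for the variant
    screen: every read maps uniquely and differs from the reference
    only at planted variants."""
    from bacplace.simulate import emit_fixture_set

    cfg = SimConfig(
        seed=5, n_clones=150, substitution_rate=0.0, n_repeat_families=0
    )
    outdir = tmp_path_factory.mktemp("clean_fixture")
    truth = emit_fixture_set(cfg, outdir)
    return {"config": cfg, "dir": outdir, "truth": truth}
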