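"""Graph building, filtering, anchors, traversal and its pruning heuristics."""

import numpy as np
import pytest

from conftest import exhaustive_traverse
from oligodbg.codec_sim import ONT_PROFILE, ZERO_PROFILE, simulate_reads
from oligodbg.dbg_consensus import (
    KmerGraph,
    break_loop,
    consensus_for_subset,
    count_kmers,
    end_anchors,
    filter_kmers,
    prune_dead_ends,
    start_kmer,
    traverse,
)
from oligodbg.formats_io import ConfigError, PipelineParams, Read
from oligodbg.partitioner import Subset, partition
from oligodbg.primer_anchor import PrimerScheme


def R(bases):
    return Read(id="r", bases=bases)


def graph_from(seqs, k, threshold=1):
    return filter_kmers(count_kmers([R(s) for s in seqs], k), threshold, k=k)


class TestCountKmers:
    def test_simple_windows(self):
        assert count_kmers([R("ACGTA")], 3) == {"ACG": 1, "CGT": 1, "GTA": 1}

    def test_saturates_at_255(self):
        counts = count_kmers([R("ACG")] * 300, 3)
        assert counts == {"ACG": 255}

    def test_short_reads_and_N_windows_skipped(self):
        assert count_kmers([R("AC")], 3) == {}
        assert count_kmers([R("ACNGT")], 3) == {}
        counts = count_kmers([R("ACGNACGT")], 3)
        assert counts == {"ACG": 2, "CGT": 1}


class TestFilterKmers:
    def test_threshold_filters(self):
        g = filter_kmers({"AAA": 2, "CCC": 3}, 3)
        assert set(g.counts) == {"CCC"}

    def test_threshold_one_is_identity(self):
        counts = {"AAA": 1, "CCC": 7}
        assert filter_kmers(counts, 1).counts == counts

    def test_empty(self):
        assert filter_kmers({}, 3).counts == {}

    def test_monotonicity(self):
        rng = np.random.default_rng(0)
        counts = {f"{i:03d}": int(c) for i, c in enumerate(rng.integers(1, 10, 50))}
        prev = set(filter_kmers(counts, 1).counts)
        for t in (2, 3, 5, 8):
            cur = set(filter_kmers(counts, t).counts)
            assert cur <= prev
            prev = cur


class TestStartKmer:
    def test_direct_lcp(self):
        scheme = PrimerScheme(pairs=(("ACGTACGTAC", "TTGACCAGTA"),), expected_length=40)
        reads = [R("ACGTACGTTT"), R("ACGTACGTAA"), R("ACGTACGCCC")]
        # LCP is ACGTACG (7 nt), within the primer cap
        assert start_kmer(reads, scheme, 0, 5) == "GTACG"

    def test_fallback_to_primer(self):
        scheme = PrimerScheme(pairs=(("ACGTACGTAC", "TTGACCAGTA"),), expected_length=40)
        reads = [R("ACGCCCCCCC"), R("ACTTTTTTTT")]  # LCP "AC" < k
        assert start_kmer(reads, scheme, 0, 5) == "CGTAC"

    def test_lcp_capped_at_primer_length(self):
        scheme = PrimerScheme(pairs=(("ACGTA", "TTGAC"),), expected_length=40)
        reads = [R("ACGTACCCCC"), R("ACGTACCCCC")]  # identical beyond the primer
        assert start_kmer(reads, scheme, 0, 3) == "GTA"

    def test_empty_subset(self):
        scheme = PrimerScheme(pairs=(("ACGTA", "TTGAC"),), expected_length=40)
        assert start_kmer([], scheme, 0, 3) is None


class TestEndAnchors:
    def test_leftmost_kmer_and_dedup(self):
        scheme = PrimerScheme(
            pairs=(("AAAAACCCCC", "TTGACCAGTA"), ("GGGGGCCCCC", "TTGACCAGTA")),
            expected_length=40,
        )
        anchors = end_anchors(scheme, 5)
        assert set(anchors) == {"TTGAC"}
        assert anchors["TTGAC"] == ("CAGTA",)

    def test_distinct_end_primers(self):
        scheme = PrimerScheme(
            pairs=(("AAAAACCCCC", "TTGACCAGTA"), ("GGGGGCCCCC", "CATGACGGTT")),
            expected_length=40,
        )
        assert len(end_anchors(scheme, 5)) == 2

    def test_end_primer_shorter_than_k_is_config_error(self):
        scheme = PrimerScheme(pairs=(("AAAAACCCCC", "TTGA"),), expected_length=40)
        with pytest.raises(ConfigError):
            end_anchors(scheme, 5)


def _linear_case(k=5):
    start_p, end_p = "ACGTACGTAC", "TTGACCAGTA"
    payload = "GGCATCCGTTAGCAAC"
    s = start_p + payload + end_p
    scheme = PrimerScheme(pairs=((start_p, end_p),), expected_length=len(s))
    params = PipelineParams(k=k, expected_length=len(s))
    return s, scheme, params


class TestTraverse:
    def test_unique_linear_path(self):
        s, scheme, params = _linear_case()
        graph = graph_from([s], params.k)
        start = scheme.pairs[0][0][-params.k:]
        out = traverse(graph, start, end_anchors(scheme, params.k), scheme, params,
                       prefix=scheme.pairs[0][0][: -params.k])
        assert out == {s}

    def test_noisy_copies_recover_reference(self, scheme, structure):
        """30 copies at ~1% substitutions, threshold 3: exactly the true
        oligo, verified against the exhaustive-DFS oracle on the same graph."""
        from oligodbg.codec_sim import NoiseProfile, generate_oligos

        oligo = generate_oligos(1, scheme, structure, seed=21)[0]
        profile = NoiseProfile(substitution_rate=0.01)
        reads, _ = simulate_reads([oligo], 30, profile, seed=4,
                                  deterministic_coverage=True)
        params = PipelineParams(expected_length=scheme.expected_length)
        graph = filter_kmers(count_kmers(reads, params.k), 3, k=params.k)
        oracle_graph = KmerGraph(k=params.k, counts=dict(graph.counts))
        primer = scheme.pairs[0][0]
        start = primer[-params.k:]
        prefix = primer[: -params.k]
        ends = end_anchors(scheme, params.k)
        out = traverse(graph, start, ends, scheme, params, prefix=prefix)
        assert out == {oligo.full_sequence}
        assert out == exhaustive_traverse(oracle_graph, start, ends, prefix,
                                          scheme.expected_length)

    def test_cycle_without_completion_terminates_empty(self):
        # a pure 4-cycle of 3-mers: ACG -> CGA -> GAC -> ACG ...
        scheme = PrimerScheme(pairs=(("AAACG", "TTTTT"),), expected_length=30)
        params = PipelineParams(k=3, expected_length=30, max_traversal_steps=10_000)
        graph = KmerGraph(k=3, counts={"ACG": 5, "CGA": 5, "GAC": 5})
        out = traverse(graph, "ACG", {"TTT": ("TT",)}, scheme, params, prefix="AA")
        assert out == set()

    def test_missing_start_kmer(self):
        s, scheme, params = _linear_case()
        graph = graph_from([s], params.k)
        out = traverse(graph, "GGGGG", end_anchors(scheme, params.k), scheme, params)
        assert out == set()


class TestBreakLoop:
    def test_edge_into_second_occurrence_removed(self):
        g = KmerGraph(k=3, counts={"ACG": 1, "CGA": 1, "GAC": 1})
        path = ["ACG", "CGA", "GAC", "ACG"]  # ACG repeats
        assert break_loop(g, path)
        assert g.deleted_edges == {("GAC", "G")}

    def test_repeat_free_path_unchanged(self):
        g = KmerGraph(k=3, counts={"ACG": 1, "CGT": 1})
        assert not break_loop(g, ["ACG", "CGT"])
        assert g.deleted_edges == set()

    def test_retraversal_of_broken_loop_impossible(self):
        """After the deletion, re-running the DFS never spells the cycle."""
        scheme = PrimerScheme(pairs=(("AAACG", "TTTTT"),), expected_length=30)
        params = PipelineParams(k=3, expected_length=30, max_traversal_steps=10_000)
        counts = {"ACG": 5, "CGA": 5, "GAC": 5}
        graph = KmerGraph(k=3, counts=dict(counts))
        traverse(graph, "ACG", {"TTT": ("TT",)}, scheme, params, prefix="AA")
        assert graph.deleted_edges  # the loop got broken
        kmer, base = next(iter(graph.deleted_edges))
        # the cyclic edge is gone: successors of the source skip the loop
        assert base not in graph.successors(kmer)


class TestPruneDeadEnds:
    def test_stub_removed_chain_kept(self):
        # chain ACG->CGT->GTA plus stub CGG (no successors)
        g = KmerGraph(k=3, counts={"ACG": 1, "CGT": 1, "GTA": 1, "CGG": 1})
        prune_dead_ends(g, protected={"GTA"})
        assert set(g.counts) == {"ACG", "CGT", "GTA"}

    def test_cycle_unchanged(self):
        g = KmerGraph(k=3, counts={"ACG": 1, "CGA": 1, "GAC": 1})
        prune_dead_ends(g)
        assert len(g.counts) == 3

    def test_empty_graph(self):
        g = KmerGraph(k=3, counts={})
        assert prune_dead_ends(g).counts == {}

    def test_cascade(self):
        # GTA is a dead end; removing it strands CGT, then ACG
        g = KmerGraph(k=3, counts={"ACG": 1, "CGT": 1, "GTA": 1})
        prune_dead_ends(g)
        assert g.counts == {}


class TestConsensusForSubset:
    def test_exact_copies_single_oligo(self, scheme, structure, params, small_oligos):
        oligo = small_oligos[0]
        reads, _ = simulate_reads([oligo], 30, ZERO_PROFILE, seed=0,
                                  deterministic_coverage=True)
        sub = Subset(0, "AAAA", 0, reads)
        out = consensus_for_subset(sub, scheme, params)
        assert {c.sequence for c in out} == {oligo.full_sequence}

    def test_two_oligos_same_primers(self, scheme, structure, params, small_oligos):
        """A subset mixing copies of two oligos recovers both; matches the
        exhaustive oracle on the merged graph."""
        pair0 = [o for o in small_oligos if o.primer_index == 0][:2]
        reads, _ = simulate_reads(pair0, 5, ZERO_PROFILE, seed=0,
                                  deterministic_coverage=True)
        sub = Subset(0, "AAAA", 0, reads)
        out = {c.sequence for c in consensus_for_subset(sub, scheme, params)}
        assert out == {o.full_sequence for o in pair0}
        graph = filter_kmers(count_kmers(reads, params.k), params.abundance_threshold)
        primer = scheme.pairs[0][0]
        oracle = exhaustive_traverse(graph, primer[-15:], end_anchors(scheme, 15),
                                     primer[:-15], scheme.expected_length)
        assert out == oracle

    def test_reads_missing_end_primer(self, scheme, params, small_oligos):
        oligo = small_oligos[0]
        clipped = [Read(id=f"c{i}", bases=oligo.full_sequence[:-30]) for i in range(10)]
        sub = Subset(0, "AAAA", 0, clipped)
        assert consensus_for_subset(sub, scheme, params) == set()

    def test_candidates_have_length_N_and_end_primer(self, scheme, params, small_oligos):
        reads, _ = simulate_reads(small_oligos, 10, ONT_PROFILE, seed=8)
        subsets, _ = partition(reads, scheme, params)
        ends = tuple(e for _s, e in scheme.pairs)
        for s in subsets:
            for c in consensus_for_subset(s, scheme, params):
                assert len(c.sequence) == scheme.expected_length
                assert c.sequence.endswith(ends)


def test_threshold_monotonicity_on_candidates(scheme, structure, small_oligos):
    """Raising the abundance threshold traverses a subgraph: the candidate
    set can lose but the graph never gains k-mers."""
    reads, _ = simulate_reads(small_oligos[:5], 30, ONT_PROFILE, seed=12)
    counts = count_kmers(reads, 15)
    prev_nodes = None
    for t in (1, 2, 3, 5):
        nodes = set(filter_kmers(counts, t).counts)
        if prev_nodes is not None:
            assert nodes <= prev_nodes
        prev_nodes = nodes
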