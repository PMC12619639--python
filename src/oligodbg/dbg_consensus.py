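"""Per-subset de Bruijn graph construction and exact-length consensus traversal.

The graph is a plain hash table of k-mer counts, saturated at 255 so counts
fit one byte, with implicit 4-way successor edges (x -> x[1:] + b). Reads
in a subset are already co-oriented, so no canonical (reverse-complement
merged) k-mers are used. After abundance filtering, consensus candidates
are all paths of total length exactly N that run from a start anchor k-mer
(derived from the subset's common prefix or the known start primer) to the
leftmost k-mer of an end primer.

The traversal is depth-first with three cost controls:

* dead-end nodes (no surviving successors) are deleted as they are found,
  and the deletion cascades backwards at backtrack time;
* when a path overruns the target length, its first repeated k-mer is
  located and the edge entering the repeat's second occurrence is removed,
  breaking the loop (lossy, but loops otherwise dominate the search);
* a per-subset step budget caps the total number of extensions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

from .formats_io import ConfigError, PipelineParams, Read
from .partitioner import Subset
from .primer_anchor import PrimerScheme

logger = logging.getLogger("oligodbg.consensus")

COUNT_CAP = 255
_BASES = "ACGT"
_BASES_REV = "TGCA"  # pushed onto stacks so pop() tries A first


@dataclasses.dataclass
class KmerGraph:
    """Abundance-filtered k-mer multiset with implicit successor edges."""

    k: int
    counts: dict[str, int]
    deleted_edges: set[tuple[str, str]] = dataclasses.field(default_factory=set)

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        deleted = self.deleted_edges
        return [
            b for b in _BASES if suffix + b in self.counts and (kmer, b) not in deleted
        ]

    def __len__(self) -> int:
        return len(self.counts)


@dataclasses.dataclass(frozen=True)
class ConsensusCandidate:
    """A reconstructed oligo of length exactly N, attributed to its subset."""

    sequence: str
    subset: str


def count_kmers(reads: list[Read], k: int) -> dict[str, int]:
    """Count every k-length window over {A,C,G,T}; saturate at 255.

    Windows containing 'N' contribute nothing. No canonicalization: reads
    are expected to be identically oriented.
    """
    counts: dict[str, int] = {}
    for read in reads:
        s = read.bases
        has_n = "N" in s
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if has_n and "N" in km:
                continue
            c = counts.get(km, 0)
            if c < COUNT_CAP:
                counts[km] = c + 1
    return counts


def filter_kmers(
    counts: dict[str, int], abundance_threshold: int, k: Optional[int] = None
) -> KmerGraph:
    """Keep exactly the k-mers with count >= abundance_threshold."""
    if abundance_threshold < 1:
        raise ConfigError("abundance_threshold must be >= 1")
    if k is None:
        k = len(next(iter(counts))) if counts else 0
    kept = {km: c for km, c in counts.items() if c >= abundance_threshold}
    return KmerGraph(k=k, counts=kept)


def start_anchor(
    reads: list[Read], scheme: PrimerScheme, primer_index: int, k: int
) -> Optional[str]:
    """The anchoring prefix whose last k bases are the start k-mer.

    This is the longest common prefix of all reads, capped at the start
    primer's length; if shorter than k it falls back to the known start
    primer itself. Returns None when no k-mer can be derived.
    """
    if not reads:
        return None
    primer = scheme.pairs[primer_index][0]
    lcp = reads[0].bases[: len(primer)]
    for r in reads[1:]:
        b = r.bases
        n = min(len(lcp), len(b))
        i = 0
        while i < n and lcp[i] == b[i]:
            i += 1
        lcp = lcp[:i]
        if not lcp:
            break
    if len(lcp) >= k:
        return lcp
    if len(primer) >= k:
        return primer
    return None


def start_kmer(
    reads: list[Read], scheme: PrimerScheme, primer_index: int, k: int
) -> Optional[str]:
    """Rightmost k-mer of the common-prefix anchor (see start_anchor)."""
    anchor = start_anchor(reads, scheme, primer_index, k)
    return None if anchor is None else anchor[-k:]


def end_anchors(scheme: PrimerScheme, k: int) -> dict[str, tuple[str, ...]]:
    """Leftmost k-mer of each end primer, mapped to the primer remainder(s).

    The keys form the set of terminal k-mers; the values carry the bases of
    each matching end primer past its first k, used to complete accepted
    candidates.
    """
    anchors: dict[str, set[str]] = {}
    for _start, end in scheme.pairs:
        if len(end) < k:
            raise ConfigError(
                f"end primer length {len(end)} is shorter than k={k}"
            )
        anchors.setdefault(end[:k], set()).add(end[k:])
    return {a: tuple(sorted(rems)) for a, rems in anchors.items()}


def break_loop(graph: KmerGraph, path_kmers: list[str]) -> bool:
    """Remove one edge to break the first repeated k-mer on a failing path.

    The edge entering the second occurrence of the first repeated k-mer is
    added to deleted_edges. Returns True if an edge was removed. Lossy:
    valid consensus paths through the deleted edge are no longer reachable.
    """
    seen: set[str] = set()
    for i, km in enumerate(path_kmers):
        if km in seen:
            graph.deleted_edges.add((path_kmers[i - 1], km[-1]))
            return True
        seen.add(km)
    return False


def prune_dead_ends(graph: KmerGraph, protected: frozenset[str] | set[str] = frozenset()) -> KmerGraph:
    """Iteratively delete nodes with no surviving successors (fixed point).

    Nodes in ``protected`` (the end anchors) are never removed: they are
    legitimate path terminals.
    """
    worklist = [km for km in graph.counts if km not in protected and not graph.successors(km)]
    while worklist:
        node = worklist.pop()
        if node not in graph.counts:
            continue
        del graph.counts[node]
        suffix = node[:-1]
        for c in _BASES:
            pred = c + suffix
            if pred in graph.counts and pred not in protected and not graph.successors(pred):
                worklist.append(pred)
    return graph


def traverse(
    graph: KmerGraph,
    start: str,
    ends: dict[str, tuple[str, ...]],
    scheme: PrimerScheme,
    params: PipelineParams,
    prefix: str = "",
) -> set[str]:
    """Enumerate all surviving length-N paths from ``start`` to an end anchor.

    A path is accepted when its last k bases equal an end anchor and
    prepending ``prefix`` plus appending that end primer's remainder gives
    total length exactly N; the candidate is completed from the known
    primer. Paths that can no longer reach length N exactly are cut, loops
    are broken, dead ends pruned, and the whole subset traversal is bounded
    by ``params.max_traversal_steps`` extensions (budget exhaustion returns
    the partial result set).
    """
    N = scheme.expected_length
    if start not in graph.counts or not ends:
        return set()
    min_rem = min(len(r) for rems in ends.values() for r in rems)
    results: set[str] = set()
    chars = list(start)
    kmers = [start]

    def check_accept(node: str) -> bool:
        rems = ends.get(node)
        if not rems:
            return False
        accepted = False
        total = len(prefix) + len(chars)
        for rem in rems:
            if total + len(rem) == N:
                results.add(prefix + "".join(chars) + rem)
                accepted = True
        return accepted

    check_accept(start)
    if len(prefix) + len(chars) + min_rem >= N:
        return results

    budget = params.max_traversal_steps
    steps = 0
    stack: list[list[str]] = [list(_BASES_REV)]
    protected = ends  # dict membership ~ set of anchor k-mers
    while stack:
        frame = stack[-1]
        if not frame:
            # backtrack; cascade dead-end pruning
            node = kmers.pop()
            stack.pop()
            if len(kmers) >= 1:
                chars.pop()
            if node not in protected and node in graph.counts and not graph.successors(node):
                del graph.counts[node]
            continue
        b = frame.pop()
        cur = kmers[-1]
        nxt = cur[1:] + b
        if nxt not in graph.counts or (cur, b) in graph.deleted_edges:
            continue
        steps += 1
        if steps > budget:
            logger.info("traversal budget (%d steps) exhausted", budget)
            break
        chars.append(b)
        kmers.append(nxt)
        accepted = check_accept(nxt)
        if len(prefix) + len(chars) + min_rem >= N:
            # path is at (or beyond) its maximal extendable length
            if not accepted:
                break_loop(graph, kmers)
            kmers.pop()
            chars.pop()
            continue
        stack.append(list(_BASES_REV))
    return results


def consensus_for_subset(
    subset: Subset, scheme: PrimerScheme, params: PipelineParams
) -> set[ConsensusCandidate]:
    """count -> filter -> anchor -> traverse for one subset.

    Subsets are independent: no shared state, so results do not depend on
    processing order or concurrency.
    """
    counts = count_kmers(subset.reads, params.k)
    graph = filter_kmers(counts, params.abundance_threshold, k=params.k)
    if not graph.counts:
        return set()
    anchor = start_anchor(subset.reads, scheme, subset.primer_index, params.k)
    if anchor is None:
        return set()
    start = anchor[-params.k :]
    prefix = anchor[: -params.k]
    ends = end_anchors(scheme, params.k)
    prune_dead_ends(graph, protected=set(ends))
    seqs = traverse(graph, start, ends, scheme, params, prefix=prefix)
    return {ConsensusCandidate(sequence=s, subset=subset.name) for s in seqs}
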