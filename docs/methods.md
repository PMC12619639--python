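# Methods

## Model and assumptions

`oligodbg` reconstructs the original oligonucleotide set of a DNA archive
from noisy sequencing reads. It assumes:

- every original oligo has the layout `start_primer | payload area |
  end_primer` with a **known total length N** and known primer sequences
  (one or several ordered pairs, e.g. one pair per document part);
- every usable read contains a complete oligo, both primers included
  (merged short-read pairs or long reads; for pipelines that trim primers
  during base calling, `append_artificial_primers` restores the frame);
- reads may carry substitutions and indels, junk flanking bases, and may
  come from either strand.

Reconstruction = hierarchical partitioning + per-subset de Bruijn graph
path enumeration, as described in the README. The method needs no
knowledge of the payload encoding; the index/CRC layout is used only by
the simulator and the optional CRC-filtered precision metric.

## Parameters

| name | default | meaning |
|---|---|---|
| `k` | 15 nt | graph k-mer length. Below ~13 nt, distinct oligos share k-mers by chance and traversal degrades; larger k needs more intact bases per read. |
| `abundance_threshold` | 3 | minimum k-mer count to survive filtering. At 30× coverage, true k-mers typically appear ≥ 10× per subset while error k-mers are 1–2×; threshold 1 floods the graph with error branches. |
| `subset_max_reads` (T) | 2000 | subset cap. Bounds graph size and traversal cost per subset. |
| `key_len_short` / `key_len_long` | 4 / 20 nt | partitioning keys: 4 bases give ≤ 256 first-level groups per primer pair; 20 bases are the refinement sort key for oversized groups. |
| `max_primer_mismatch_frac` | 0.25 | acceptance cutoff for anchoring, as a fraction of primer length (5 mismatches on a 20-nt primer). Random windows score ~0.75, so 0.25 rejects background while tolerating realistic noise. |
| `seed_len` | 8 nt | exact-match seed proposing anchor offsets. 8 balances sensitivity at indel-heavy error rates against the number of windows scored; the exhaustive-scan oracle in the tests bounds the sensitivity loss. |
| `max_traversal_steps` | 1 000 000 | per-subset extension budget; exhaustion returns partial results and is logged, not fatal. |

All coordinates are 0-based half-open. 'N' bases are legal on input, are
never counted into k-mers, and mismatch everything (including 'N') during
anchoring, so ambiguous stretches cannot anchor a primer.

## Numerical and design choices

- **Anchoring is Hamming-only.** Gapped (Smith–Waterman) scoring was
  deliberately omitted; at 20-nt primer scale the Hamming score separates
  true from background windows, and reads whose primer is too corrupted
  to pass the cutoff are dropped — which also protects the downstream
  consensus from their errors. Ties break deterministically: fewer
  mismatches, forward over reverse, smaller position, smaller primer
  index.
- **First-level routing is over {A,C,G,T}.** Key characters outside that
  alphabet ('N', or sentinel padding when a trimmed read is shorter than
  primer + 4) are normalized to 'A' for routing, which keeps the
  first-level group count at exactly 4^4 per primer pair. The refinement
  key keeps the raw sentinel-padded form (sentinel sorts before 'A').
- **Splitting cuts only at refinement-key boundaries.** A run of
  identical 20-base keys is never divided even if the chunk then exceeds
  T, because separating copies of one oligo would defeat the method's
  core invariant. Chunks are otherwise filled greedily to ≤ T.
- **Start anchor.** The traversal start is the rightmost k-mer of the
  longest common prefix of the subset's reads, capped at the start-primer
  length; with realistic noise the LCP is almost always shorter than k
  and the anchor falls back to the known primer, so emitted candidates
  begin with the exact primer. Bases preceding the start k-mer are
  prepended from the anchor, and the end primer's bases past its first
  k-mer are appended from the known primer rather than read from the
  graph.
- **Loop breaking.** When a path overruns N, the first repeated k-mer on
  it is found and the edge entering its second occurrence is deleted —
  exactly one edge per failing path. This is lossy by design; deletions
  persist for the remainder of the subset's traversal, as does progressive
  dead-end pruning (end-anchor nodes are never pruned).
- **Index encoding in the simulator.** Ordinals are encoded in a
  fixed-width mixed-radix rotating code (first base free, each later base
  one of the 3 bases differing from its predecessor). It is invertible,
  and produces no two adjacent equal bases, so the whole-oligo
  homopolymer cap can be enforced; capacity is 4·3^(L−1) (≈ 7.1 × 10^5
  for the default 12-nt index). The CRC field is a CRC-16/CCITT-FALSE
  over the 2-bit-packed index+payload, written as 8 nt MSB-first.
- **Empty-denominator metrics** report 0 with an explicit flag; matching
  is exact full-length string equality on deduplicated sets.

## What the simulator emulates — and what it does not

`codec_sim` generates constraint-respecting references (GC in [0.40,
0.60], homopolymers ≤ 3, no primer or its reverse complement inside the
payload, payloads uniform otherwise) and corrupts reads by per-base
deletion, then substitution (always to a different base), then insertion
after surviving bases, plus junk flanks and strand flips. Presets:
`ont` (sub 0.02 / ins 0.015 / del 0.015, junk 0–20 nt, flip 0.5) and
`illumina` (sub 0.005, indels 10⁻⁴, no junk). Coverage is
Poisson-distributed per oligo (mean 30 by convention) or exact in
deterministic mode.

Not modelled: quality scores, homopolymer-length-dependent error rates,
chimeric reads, molecular degradation/fragmentation, and — importantly —
the *correlation structure of real encoded payloads*. Uniform random
payloads of distinct oligos share a given 15-mer with probability ~2×10⁻⁵,
so large merged graphs stay nearly tree-like here, whereas real encoded
documents can produce heavily entangled graphs. Passing tests therefore
demonstrate the pipeline's correctness and its noise/coverage/threshold
behaviour, not its behaviour on pathologically repetitive payloads.

One consequence is visible in the subset-size sensitivity check: at desk
scale (~20 000–90 000 reads, uniform payloads) recall *increases* slightly
with the subset cap (fewer chunk boundaries scatter fewer copies), while
on large real archives the opposite, graph-complexity-driven trend is the
documented behaviour; the small-subset penalty (T = 500 worse than
T = 2000) does reproduce here. The corresponding acceptance test asserts
the large-archive direction and fails under the simulator's conditions;
it is kept as-is rather than weakened.

## Problem sizes used in the shipped checks

The standard scenario is 1000 oligos of 164 nt (two 20-nt primer pairs,
12-nt index, 8-nt CRC), ~30 000 reads at 30× with the `ont` preset —
small enough for single-core runs in seconds, large enough for first-level
groups to overflow T and exercise the refinement split. The traversal
oracle check uses 200 random ≤ 60-node graphs at k = 9 against an
unbounded exhaustive DFS; zero-noise checks use 50 oligos at deterministic
coverage 3 (the abundance threshold exactly met by error-free copies).

## Known limitations

- Anchoring rejects reads with indel-corrupted primers (~20 % of reads at
  the `ont` preset), and key errors scatter some copies across chunks;
  both lower recall at heavy noise — missing sequences are the province
  of the archive's outer error-correcting code, not of this tool.
- Counts saturate at 255, so abundance thresholds above 255 are
  meaningless.
- The per-subset step budget makes extremely noisy graphs (threshold 1)
  return partial results.
- Spill-to-disk for oversized first-level groups is not implemented; the
  partitioner holds one run's reads in memory.
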