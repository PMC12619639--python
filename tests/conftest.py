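"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (exhaustive scans, bit-serial CRC,
unbounded DFS) and independent of the package's code paths they check.
"""

from __future__ import annotations

import pytest

from oligodbg.codec_sim import OligoStructure, design_primer_pairs, generate_oligos
from oligodbg.formats_io import PipelineParams
from oligodbg.primer_anchor import PrimerScheme, hamming, reverse_complement


@pytest.fixture(scope="session")
def scheme() -> PrimerScheme:
    """Two 20-nt primer pairs, 164-nt oligos."""
    pairs = design_primer_pairs(2, length=20, seed=7)
    return PrimerScheme(pairs=tuple(pairs), expected_length=164)


@pytest.fixture(scope="session")
def structure() -> OligoStructure:
    return OligoStructure(index_len=12, crc_len=8)


@pytest.fixture(scope="session")
def small_oligos(scheme, structure):
    return generate_oligos(20, scheme, structure, seed=3)


@pytest.fixture
def params() -> PipelineParams:
    return PipelineParams(expected_length=164)


# --- oracles -----------------------------------------------------------------

def brute_force_anchor(bases: str, scheme: PrimerScheme, frac: float):
    """Score every offset of every start primer on both strands; return the
    global best (mismatches, orientation_rank, position, primer_index) that
    passes the mismatch threshold, or None."""
    import math

    best = None
    for orank, target in ((0, bases), (1, reverse_complement(bases))):
        for pi, (sp, _e) in enumerate(scheme.pairs):
            limit = math.floor(frac * len(sp))
            for pos in range(len(target) - len(sp) + 1):
                mm = hamming(sp, target[pos : pos + len(sp)])
                if mm <= limit:
                    key = (mm, orank, pos, pi)
                    if best is None or key < best:
                        best = key
    return best


def crc16_bit_serial(data: bytes) -> int:
    """Bit-serial CRC-16/CCITT-FALSE: shift each message bit through the
    register, XOR with the polynomial on carry-out. Independent of the
    package's byte-wise loop."""
    poly = 0x1021
    reg = 0xFFFF
    for byte in data:
        for bit in range(7, -1, -1):
            msg_bit = (byte >> bit) & 1
            carry = (reg >> 15) & 1
            reg = ((reg << 1) & 0xFFFF) | 0
            if carry ^ msg_bit:
                reg ^= poly
    return reg


def exhaustive_traverse(graph, start: str, ends: dict, prefix: str, N: int) -> set[str]:
    """Enumerate every length-N completion by plain recursion: no loop
    breaking, no pruning, no step budget. Termination is guaranteed by the
    length cap alone."""
    results: set[str] = set()
    if start not in graph.counts:
        return results

    def extend(kmer: str, seq: list[str]):
        total = len(prefix) + len(seq)
        rems = ends.get(kmer)
        if rems:
            for rem in rems:
                if total + len(rem) == N:
                    results.add(prefix + "".join(seq) + rem)
        if total >= N:  # cannot grow into any exact completion
            return
        suffix = kmer[1:]
        for b in "ACGT":
            nxt = suffix + b
            if nxt in graph.counts:
                seq.append(b)
                extend(nxt, seq)
                seq.pop()

    extend(start, list(start))
    return results
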