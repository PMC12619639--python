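"""Synthetic DNA-storage dataset generation and read simulation.

Ground-truth oligos follow the common storage layout

    start_primer | index_field | payload | crc_field | end_primer

with a total length N. The index field encodes the oligo's ordinal with a
rotating mixed-radix code (first base free, each subsequent base one of the
three bases differing from its predecessor), which is invertible and
introduces no adjacent equal bases — important because the whole oligo must
respect a homopolymer cap. The CRC field is a CRC-16/CCITT-FALSE over the
2-bit-packed index+payload, written as 8 nt at 2 bits per base.

Read simulation applies, per source base: deletion, then substitution (to a
*different* base), then possibly an insertion after the surviving base;
junk flanks and random strand flips complete the read. Presets emulate an
indel-heavy long-read instrument ("ont") and a substitution-dominated
short-read one ("illumina") at order-of-magnitude realistic rates; quality
strings are not modelled (the pipeline never reads them).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np
from Bio.SeqUtils import gc_fraction

from .formats_io import ConfigError, Read
from .primer_anchor import PrimerScheme, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


# --- CRC-16/CCITT-FALSE ------------------------------------------------------

def crc16(data: bytes) -> int:
    """CRC-16/CCITT-FALSE: poly 0x1021, init 0xFFFF, no reflection, xorout 0.

    crc16(b"123456789") == 0x29B1.
    """
    crc = 0xFFFF
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021 if crc & 0x8000 else crc << 1) & 0xFFFF
    return crc


def pack_bases(seq: str) -> bytes:
    """2-bit pack (A=00, C=01, G=10, T=11), zero-padded to a whole byte."""
    acc = 0
    out = bytearray()
    nbits = 0
    for b in seq:
        acc = (acc << 2) | _BASE_INDEX[b]
        nbits += 2
        if nbits == 8:
            out.append(acc)
            acc = 0
            nbits = 0
    if nbits:
        out.append(acc << (8 - nbits))
    return bytes(out)


def crc_field(index_payload: str, crc_len: int = 8) -> str:
    """CRC-16 of the 2-bit-packed sequence, encoded MSB-first at 2 bits/base."""
    if crc_len * 2 < 16:
        raise ConfigError(f"crc_len {crc_len} cannot hold 16 bits")
    value = crc16(pack_bases(index_payload))
    out = []
    for i in range(crc_len):
        shift = 2 * (crc_len - 1 - i)
        out.append(BASES[(value >> shift) & 0x3] if shift < 16 else "A")
    return "".join(out)


# --- index encoding ----------------------------------------------------------

def index_capacity(length: int) -> int:
    """Number of ordinals encodable in ``length`` bases (4 * 3^(length-1))."""
    if length < 1:
        return 0
    return 4 * 3 ** (length - 1)


def encode_ordinal(ordinal: int, length: int) -> str:
    """Homopolymer-free fixed-width encoding of an ordinal.

    First base is one of 4; every later base is one of the 3 bases that
    differ from its predecessor, so the field never contains two adjacent
    equal bases. Inverse: :func:`decode_ordinal`.
    """
    cap = index_capacity(length)
    if not 0 <= ordinal < cap:
        raise ConfigError(
            f"ordinal {ordinal} not representable in {length} bases (capacity {cap})"
        )
    radix = 3 ** (length - 1)
    out = [BASES[ordinal // radix]]
    rem = ordinal % radix
    for i in range(1, length):
        radix //= 3
        digit = rem // radix
        rem %= radix
        choices = [b for b in BASES if b != out[-1]]
        out.append(choices[digit])
    return "".join(out)


def decode_ordinal(field: str) -> int:
    ordinal = _BASE_INDEX[field[0]]
    for prev, cur in zip(field, field[1:]):
        choices = [b for b in BASES if b != prev]
        ordinal = ordinal * 3 + choices.index(cur)
    return ordinal


# --- oligo generation --------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class OligoStructure:
    """Field widths of the payload area (index | payload | crc)."""

    index_len: int = 12
    crc_len: int = 8

    def payload_len(self, scheme: PrimerScheme, primer_index: int) -> int:
        s, e = scheme.pairs[primer_index]
        n = scheme.expected_length - len(s) - len(e) - self.index_len - self.crc_len
        if n < 1:
            raise ConfigError("field widths leave no room for a payload")
        return n


@dataclasses.dataclass(frozen=True)
class OligoRecord:
    """One ground-truth reference oligo."""

    ordinal: int
    primer_index: int
    index_field: str
    payload: str
    crc_field: str
    full_sequence: str


def max_homopolymer(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def validate_crc(
    seq: str, scheme: PrimerScheme, structure: OligoStructure
) -> bool:
    """Check the embedded CRC field of a full-length sequence.

    The sequence is accepted if, for any primer pair of the scheme, stripping
    that pair's primers and the CRC field leaves an index+payload whose
    CRC-16 matches the stored field.
    """
    for s, e in scheme.pairs:
        body = seq[len(s) : len(seq) - len(e)]
        if len(body) <= structure.crc_len:
            continue
        index_payload = body[: -structure.crc_len]
        stored = body[-structure.crc_len :]
        if crc_field(index_payload, structure.crc_len) == stored:
            return True
    return False


def generate_oligos(
    n: int,
    scheme: PrimerScheme,
    structure: OligoStructure = OligoStructure(),
    gc_bounds: tuple[float, float] = (0.40, 0.60),
    homopolymer_cap: int = 3,
    seed: int = 0,
    max_attempts: int = 1000,
) -> list[OligoRecord]:
    """Generate n constraint-respecting reference oligos, deterministically.

    Payloads are drawn uniformly and rejection-sampled until the full
    sequence has GC within ``gc_bounds``, no homopolymer longer than
    ``homopolymer_cap``, and the payload contains no primer (or primer
    reverse complement) of the scheme. Oligo i is assigned to primer pair
    ``i * n_pairs // n`` (contiguous blocks, as when a large file is split
    into separately primed parts).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if n > index_capacity(structure.index_len):
        raise ConfigError(
            f"n={n} exceeds index capacity {index_capacity(structure.index_len)} "
            f"of a {structure.index_len}-nt index"
        )
    rng = np.random.default_rng(seed)
    forbidden = []
    for s, e in scheme.pairs:
        forbidden += [s, e, reverse_complement(s), reverse_complement(e)]
    records = []
    npairs = len(scheme.pairs)
    for i in range(n):
        pi = i * npairs // n
        start, end = scheme.pairs[pi]
        plen = structure.payload_len(scheme, pi)
        index_field = encode_ordinal(i, structure.index_len)
        for attempt in range(max_attempts):
            payload = "".join(
                BASES[c] for c in rng.integers(0, 4, size=plen)
            )
            crc = crc_field(index_field + payload, structure.crc_len)
            full = start + index_field + payload + crc + end
            lo, hi = gc_bounds
            if not lo <= gc_fraction(full) <= hi:
                continue
            if max_homopolymer(full) > homopolymer_cap:
                continue
            if any(f in payload for f in forbidden):
                continue
            records.append(
                OligoRecord(i, pi, index_field, payload, crc, full)
            )
            break
        else:
            raise ConfigError(
                f"could not satisfy constraints for oligo {i} after "
                f"{max_attempts} attempts; consider relaxing gc_bounds or the "
                "homopolymer cap"
            )
    return records


# --- read simulation ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NoiseProfile:
    """Per-base corruption rates and read-level framing noise."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    junk_prefix_range: tuple[int, int] = (0, 0)
    junk_suffix_range: tuple[int, int] = (0, 0)
    strand_flip_prob: float = 0.0

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate,
                  self.strand_flip_prob):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"noise rate {r} outside [0, 1]")


ONT_PROFILE = NoiseProfile(
    substitution_rate=0.02,
    insertion_rate=0.015,
    deletion_rate=0.015,
    junk_prefix_range=(0, 20),
    junk_suffix_range=(0, 20),
    strand_flip_prob=0.5,
)

ILLUMINA_PROFILE = NoiseProfile(
    substitution_rate=0.005,
    insertion_rate=0.0001,
    deletion_rate=0.0001,
    junk_prefix_range=(0, 0),
    junk_suffix_range=(0, 0),
    strand_flip_prob=0.5,
)

ZERO_PROFILE = NoiseProfile()

PROFILES = {"ont": ONT_PROFILE, "illumina": ILLUMINA_PROFILE, "zero": ZERO_PROFILE}


def _codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def _decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


def corrupt(seq: str, profile: NoiseProfile, rng: np.random.Generator) -> str:
    """Apply deletions, then substitutions, then insertions (in that order)."""
    L = len(seq)
    if L == 0:
        return seq
    codes = _codes(seq)
    keep = rng.random(L) >= profile.deletion_rate
    sub = rng.random(L) < profile.substitution_rate
    offsets = rng.integers(1, 4, size=L).astype(np.uint8)
    ins = rng.random(L) < profile.insertion_rate
    ins_bases = rng.integers(0, 4, size=L).astype(np.uint8)

    codes = codes.copy()
    codes[sub] = (codes[sub] + offsets[sub]) % 4
    codes = codes[keep]
    ins = ins[keep]
    ins_bases = ins_bases[keep]
    counts = 1 + ins.astype(np.int64)
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    starts = np.cumsum(counts) - counts
    out[starts] = codes
    out[starts[ins] + 1] = ins_bases[ins]
    return _decode(out)


def simulate_reads(
    oligos: list[OligoRecord],
    coverage: float,
    profile: NoiseProfile,
    seed: int = 0,
    deterministic_coverage: bool = False,
) -> tuple[list[Read], dict[str, int]]:
    """Simulate noisy reads; returns (reads, truth map read id -> ordinal).

    Per-oligo read counts are Poisson(coverage) unless
    ``deterministic_coverage`` forces exactly round(coverage) copies. Each
    read is junk_prefix + corrupted(full_sequence) + junk_suffix, reverse
    complemented with probability ``strand_flip_prob``.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth: dict[str, int] = {}
    for rec in oligos:
        ncopies = (
            int(round(coverage))
            if deterministic_coverage
            else int(rng.poisson(coverage))
        )
        for j in range(ncopies):
            body = corrupt(rec.full_sequence, profile, rng)
            lo, hi = profile.junk_prefix_range
            npre = int(rng.integers(lo, hi + 1)) if hi > 0 else lo
            lo, hi = profile.junk_suffix_range
            nsuf = int(rng.integers(lo, hi + 1)) if hi > 0 else lo
            pre = _decode(rng.integers(0, 4, size=npre).astype(np.uint8)) if npre else ""
            suf = _decode(rng.integers(0, 4, size=nsuf).astype(np.uint8)) if nsuf else ""
            bases = pre + body + suf
            if profile.strand_flip_prob and rng.random() < profile.strand_flip_prob:
                bases = reverse_complement(bases)
            rid = f"r{rec.ordinal:07d}_{j:03d}"
            reads.append(Read(id=rid, bases=bases))
            truth[rid] = rec.ordinal
    return reads, truth


def append_artificial_primers(
    reads: Iterable[Read], scheme: PrimerScheme, primer_index: int = 0
) -> Iterable[Read]:
    """Frame primer-free, co-oriented reads with the scheme's primers.

    This restores the expected read structure for inputs (e.g. merged
    short-read pairs) whose primers were removed upstream.
    """
    start, end = scheme.pairs[primer_index]
    for r in reads:
        yield Read(id=r.id, bases=start + r.bases + end, quality=None)


def design_primer_pairs(
    n_pairs: int,
    length: int = 20,
    seed: int = 0,
    gc_bounds: tuple[float, float] = (0.40, 0.60),
    homopolymer_cap: int = 2,
    max_attempts: int = 10_000,
) -> list[tuple[str, str]]:
    """Draw distinct primer pairs meeting GC and homopolymer constraints.

    The homopolymer cap of 2 within a primer guarantees that any abutting
    field base extends a run to at most 3.
    """
    rng = np.random.default_rng(seed)
    primers: list[str] = []
    lo, hi = gc_bounds
    for _ in range(max_attempts):
        if len(primers) >= 2 * n_pairs:
            break
        cand = _decode(rng.integers(0, 4, size=length).astype(np.uint8))
        if not lo <= gc_fraction(cand) <= hi:
            continue
        if max_homopolymer(cand) > homopolymer_cap:
            continue
        if cand in primers or reverse_complement(cand) in primers:
            continue
        primers.append(cand)
    if len(primers) < 2 * n_pairs:
        raise ConfigError("could not design enough primers; relax constraints")
    return [(primers[2 * i], primers[2 * i + 1]) for i in range(n_pairs)]
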