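"""Primer anchoring: locate the start primer in a read on either strand.

Candidate offsets are proposed by exact seed matches (default 8-mers)
between the read and each start primer, then scored by Hamming distance.
Gapped alignment is deliberately not used: at the primer lengths involved a
plain Hamming score separates true occurrences from background, and the
seed stage bounds the number of windows scored.

'N' mismatches every base, including 'N' itself, so ambiguous stretches can
never anchor a primer.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional

from .formats_io import ConfigError, PipelineParams, Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PRIMER_BASES = frozenset("ACGT")

FORWARD = "forward"
REVERSE = "reverse"


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution, N maps to N."""
    if not frozenset(s) <= frozenset("ACGTN"):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"illegal base(s) in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions; 'N' mismatches everything (even 'N')."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} != {len(b)}")
    return sum(x != y or x == "N" for x, y in zip(a, b))


@dataclasses.dataclass(frozen=True)
class PrimerScheme:
    """Ordered start/end primer pairs plus the expected oligo length N."""

    pairs: tuple[tuple[str, str], ...]
    expected_length: int

    def __post_init__(self):
        if not self.pairs:
            raise ConfigError("primer scheme needs at least one primer pair")
        starts = [s for s, _ in self.pairs]
        for s, e in self.pairs:
            if not s or not e:
                raise ConfigError("primers must be non-empty")
            if not _PRIMER_BASES.issuperset(s) or not _PRIMER_BASES.issuperset(e):
                raise ConfigError("primers must be over {A,C,G,T}")
            if self.expected_length <= len(s) + len(e):
                raise ConfigError(
                    f"expected_length {self.expected_length} must exceed combined "
                    f"primer lengths {len(s) + len(e)}"
                )
        if len(set(starts)) != len(starts):
            raise ConfigError("start primers must be pairwise distinct")


def load_primer_scheme(path: str | Path, expected_length: int) -> PrimerScheme:
    """Load a TSV of start_primer / end_primer columns, one pair per line.

    A header line is skipped if its fields are not nucleotide strings.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ConfigError(f"{path}:{lineno}: expected 2 tab-separated columns")
            s, e = fields[0].strip().upper(), fields[1].strip().upper()
            if not (_PRIMER_BASES.issuperset(s) and _PRIMER_BASES.issuperset(e)):
                if lineno == 1:  # header
                    continue
                raise ConfigError(f"{path}:{lineno}: non-nucleotide primer")
            pairs.append((s, e))
    return PrimerScheme(pairs=tuple(pairs), expected_length=expected_length)


@dataclasses.dataclass(frozen=True)
class AnchorHit:
    """Best start-primer occurrence in a read.

    ``position`` is the 0-based offset of the primer's first base in the
    read *after* orienting it (i.e. in the reverse-complemented read when
    ``orientation == "reverse"``).
    """

    primer_index: int
    position: int
    orientation: str
    mismatches: int


def _seed_index(target: str, seed_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for p in range(len(target) - seed_len + 1):
        index.setdefault(target[p : p + seed_len], []).append(p)
    return index


def find_anchor(
    read: Read, scheme: PrimerScheme, params: PipelineParams
) -> Optional[AnchorHit]:
    """Best start-primer hit over both strands, or None.

    Candidate offsets come from exact seed_len-mer matches between the read
    and each start primer; each candidate window is Hamming-scored and the
    minimum-mismatch hit is returned if it passes
    floor(max_primer_mismatch_frac * primer length). Ties break by fewer
    mismatches, forward over reverse, smaller position, smaller primer index.
    """
    sl = params.seed_len
    if len(read.bases) < sl:
        return None
    best: Optional[tuple[tuple[int, int, int, int], AnchorHit]] = None
    for orient_rank, orientation in ((0, FORWARD), (1, REVERSE)):
        target = read.bases if orientation == FORWARD else reverse_complement(read.bases)
        index = _seed_index(target, sl)
        for pi, (start_primer, _end) in enumerate(scheme.pairs):
            plen = len(start_primer)
            if plen < sl:
                continue
            limit = math.floor(params.max_primer_mismatch_frac * plen)
            seen: set[int] = set()
            for j in range(plen - sl + 1):
                for p in index.get(start_primer[j : j + sl], ()):
                    cand = p - j
                    if cand < 0 or cand + plen > len(target) or cand in seen:
                        continue
                    seen.add(cand)
                    mm = hamming(start_primer, target[cand : cand + plen])
                    if mm > limit:
                        continue
                    key = (mm, orient_rank, cand, pi)
                    if best is None or key < best[0]:
                        best = (key, AnchorHit(pi, cand, orientation, mm))
    return None if best is None else best[1]


def trim_and_orient(read: Read, hit: AnchorHit, scheme: PrimerScheme) -> Read:
    """Reorient (if reverse) and trim a read to [position, position + N).

    The output starts with the (noisy) start primer; it is shorter than N
    when the read ends early, and is never padded.
    """
    bases = read.bases
    quality = read.quality
    if hit.orientation == REVERSE:
        bases = reverse_complement(bases)
        quality = quality[::-1] if quality is not None else None
    start = hit.position
    stop = start + scheme.expected_length
    return Read(
        id=read.id,
        bases=bases[start:stop],
        quality=quality[start:stop] if quality is not None else None,
    )
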