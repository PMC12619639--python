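"""Hierarchical partitioning of anchored reads into bounded-size subsets.

Every trimmed read is routed by (best primer pair, 4 bases following the
primer), giving at most 256 first-level groups per primer pair. Groups
above the subset cap T are re-keyed at 20 bases, sorted by key, and split
at key boundaries into chunks of at most T reads, so that all reads sharing
a refined key stay together — the point of the whole exercise is that every
copy of one original oligo lands in one subset.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

from .formats_io import PipelineParams, Read
from .primer_anchor import PrimerScheme, find_anchor, trim_and_orient

logger = logging.getLogger("oligodbg.partition")

#: pad symbol for keys of reads too short to provide key_len bases;
#: sorts before 'A' bytewise.
KEY_SENTINEL = "-"

_ROUTE_TABLE = str.maketrans({c: "A" for c in "N" + KEY_SENTINEL})


@dataclasses.dataclass
class Subset:
    """A bounded group of trimmed, identically oriented reads."""

    primer_index: int
    first_level_key: str
    chunk_index: int
    reads: list[Read]

    @property
    def name(self) -> str:
        from .formats_io import subset_filename

        return subset_filename(self.primer_index, self.first_level_key, self.chunk_index)


def extract_key(
    trimmed: Read, scheme: PrimerScheme, key_len: int, primer_index: int = 0
) -> str:
    """Partitioning key: the ``key_len`` bases immediately after the primer.

    Reads too short to supply the full key are right-padded with a sentinel
    that sorts before 'A'.
    """
    plen = len(scheme.pairs[primer_index][0])
    key = trimmed.bases[plen : plen + key_len]
    if len(key) < key_len:
        key = key + KEY_SENTINEL * (key_len - len(key))
    return key


def _route_key(key: str) -> str:
    """First-level routing key, normalized onto the {A,C,G,T} alphabet.

    Mapping 'N' and sentinel padding to 'A' keeps the first-level key space
    at exactly 4^key_len_short (256 groups for 4 bases) per primer pair.
    """
    return key.translate(_ROUTE_TABLE)


def partition(
    reads: Iterable[Read], scheme: PrimerScheme, params: PipelineParams
) -> tuple[list[Subset], int]:
    """Anchor, trim and distribute reads into subsets; returns (subsets, unassigned).

    Reads without an acceptable primer hit are counted as unassigned and
    dropped. Within a split first-level group, all reads sharing a refined
    (key_len_long) key end up in the same chunk, even if that chunk then
    exceeds T.
    """
    T = params.subset_max_reads
    groups: dict[tuple[int, str], list[Read]] = {}
    unassigned = 0
    total = 0
    for read in reads:
        total += 1
        hit = find_anchor(read, scheme, params)
        if hit is None:
            unassigned += 1
            continue
        trimmed = trim_and_orient(read, hit, scheme)
        key4 = _route_key(
            extract_key(trimmed, scheme, params.key_len_short, hit.primer_index)
        )
        groups.setdefault((hit.primer_index, key4), []).append(trimmed)

    subsets: list[Subset] = []
    for (pi, key4), members in sorted(groups.items()):
        if len(members) <= T:
            subsets.append(Subset(pi, key4, 0, members))
            continue
        # refine: sort by the long key (stable) and split at key boundaries
        keyed = [(extract_key(r, scheme, params.key_len_long, pi), r) for r in members]
        keyed.sort(key=lambda kr: kr[0])
        chunks: list[list[Read]] = []
        current: list[Read] = []
        run: list[Read] = []
        run_key: str | None = None
        for key, r in keyed:
            if key != run_key:
                if run:
                    if current and len(current) + len(run) > T:
                        chunks.append(current)
                        current = []
                    current.extend(run)
                run = []
                run_key = key
            run.append(r)
        if run:
            if current and len(current) + len(run) > T:
                chunks.append(current)
                current = []
            current.extend(run)
        if current:
            chunks.append(current)
        for ci, chunk in enumerate(chunks):
            subsets.append(Subset(pi, key4, ci, chunk))

    assigned = sum(len(s.reads) for s in subsets)
    assert assigned + unassigned == total
    logger.info(
        "partitioned %d reads into %d subsets (%d unassigned)",
        total,
        len(subsets),
        unassigned,
    )
    return subsets, unassigned
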